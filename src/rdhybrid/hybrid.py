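"""The hybrid continuous-discrete simulation algorithm.

Each step advances the system from t0 to the time t of the next reaction:

1.  Draw r1 and solve P_R(t) = r1, where P_R(t) = exp(-sum_lj abar_lj(t))
    and abar_lj integrates the propensity of reaction (l, j) along the mean
    diffusion trajectory (diffusive species follow their deterministic
    compartment concentrations, others stay at the t0 state).
2.  Per diffusive species, split the domain adaptively: compartments whose
    expected jump count Lambda*phi stays above the cut-off T_A form the
    Gaussian region; the rest (low copy numbers, where a Gaussian poorly
    matches the Poisson jump statistics) are simulated by the diffusion-only
    SSA behind a reflective wall.
3.  Sample the correlated Gaussian flux fluctuations for the Gaussian region
    (covariance from the Lyapunov equation), apply the resulting jump
    counts, feed the mean flux across the interface, and round the updated
    counts to the nearest non-negative integers.
4.  Fire one reaction chosen proportionally to abar_lj(t), and repeat.

If the cumulative propensity never reaches -ln r1 before the step cap, the
step is a diffusion-only update flagged "no reaction".

:func:`hybrid_step` is the readable reference implementation built on the
public :mod:`rdhybrid.flux` API (edge-space covariance, literal submatrix
sampling).  :func:`hybrid_simulate` runs whole trajectories through the
compiled kernel, whose reduced (compartment-space) Gaussian sampling is
distribution-identical; the equivalence is exercised in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import scipy.optimize

from . import _kernels
from .flux import FluxSolution, build_flux_ode, flux_covariance, sample_flux_noise, solve_mean_flux
from .model import ReactionDiffusionModel, SystemState
from .ssa import Trajectory, _check_sampling, _resolve_seed, ssa_diffusion_only

__all__ = [
    "HybridConfig",
    "RegionSplit",
    "integrated_propensities",
    "survival_probability",
    "draw_next_reaction_time",
    "adaptive_cutoff",
    "split_from_column_fluxes",
    "select_reaction",
    "hybrid_step",
    "hybrid_simulate",
]

ADAPTIVITY_MODES = {"monotone": 0, "central_peak": 1, "none": 2, "ssa": 3}


@dataclass(frozen=True)
class HybridConfig:
    """Tunables of the hybrid method.

    ``ta``: cut-off T_A on the expected jump count Lambda*phi below which a
    compartment's diffusion reverts to the SSA (default 10, where the
    Poisson/Gaussian densities differ by < 0.01).
    ``quadrature_points``: trapezoid nodes for the survival integral.
    ``max_step``: cap on t - t0 (the remaining sampling horizon always caps).
    ``adaptivity_mode``: 'monotone' | 'central_peak' | 'none' (Gaussian
    everywhere) | 'ssa' (Gaussian nowhere), or a mapping species -> mode.
    """

    ta: float = 10.0
    quadrature_points: int = 33
    max_step: float = math.inf
    adaptivity_mode: str | Mapping[str, str] = "monotone"
    root_tol: float = 1e-6
    psd_repair_tol: float = 1e-10
    trace_steps: int = 0

    def __post_init__(self) -> None:
        if not self.ta > 0:
            raise ValueError("T_A must be > 0")
        if self.quadrature_points < 3:
            raise ValueError("quadrature_points must be >= 3")
        modes = (
            [self.adaptivity_mode]
            if isinstance(self.adaptivity_mode, str)
            else list(self.adaptivity_mode.values())
        )
        for m in modes:
            if m not in ADAPTIVITY_MODES:
                raise ValueError(f"unknown adaptivity mode {m!r}")

    def mode_for(self, species: str) -> str:
        if isinstance(self.adaptivity_mode, str):
            return self.adaptivity_mode
        return self.adaptivity_mode.get(species, "monotone")


@dataclass(frozen=True)
class RegionSplit:
    """Gaussian-approximation region of one species at one step.

    ``cols`` holds the inclusive 0-based x-column range [g1, g2] of the
    Gaussian region (g1 > g2 means SSA everywhere).  In the monotone mode
    g1 = 0 and the 1-based SSA cut-off is ``kg`` = g2 + 2 (K + 1 when the
    Gaussian region covers the whole domain).
    """

    species: str
    cols: tuple[int, int]
    n_cols: int

    @property
    def is_empty(self) -> bool:
        return self.cols[0] > self.cols[1]

    @property
    def is_full(self) -> bool:
        return self.cols[0] == 0 and self.cols[1] == self.n_cols - 1

    @property
    def kg(self) -> int:
        """1-based first SSA column (monotone convention); n_cols+1 if none."""
        if self.is_empty:
            return 1
        return self.cols[1] + 2

    def gaussian_mask(self, xcol: np.ndarray) -> np.ndarray:
        g1, g2 = self.cols
        return (xcol >= g1) & (xcol <= g2)


@dataclass
class StepInfo:
    t: float
    dt: float
    no_reaction: bool
    reaction: tuple[int, int] | None
    splits: dict
    clamp_loss: float = 0.0


# ---------------------------------------------------------------------------
# propensity integrals and reaction-time sampling
# ---------------------------------------------------------------------------


def _displaced_counts(model, state, flux_solutions, tau: float) -> np.ndarray:
    """Counts along the mean trajectory: diffusive species at Lambda m(tau),
    everything else frozen at the t0 state; clamped at zero."""
    cm = model.compiled()
    X = state.counts.astype(float)
    for sp, sol in flux_solutions.items():
        i = model.species_index(sp)
        m = sol.ode.mean_concentration(tau)
        X[:, i] = np.clip(cm.lam[i] * m, 0.0, None)
    return X


def _propensity_matrix(model, X: np.ndarray) -> np.ndarray:
    """(K, R) mass-action propensities at (possibly real-valued) counts."""
    cm = model.compiled()
    K, R = cm.pref.shape
    a = cm.pref.copy()
    for r in range(R):
        for i in range(cm.S):
            s = cm.stoich[r, i]
            for m in range(s):
                a[:, r] *= np.clip(X[:, i] - m, 0.0, None)
    return a


def integrated_propensities(
    model: ReactionDiffusionModel,
    state_at_t0: SystemState,
    flux_solutions: Mapping[str, FluxSolution],
    t: float,
    config: HybridConfig,
) -> tuple[np.ndarray, float]:
    """abar[k, r] = int_{t0}^{t} a_kr(mean trajectory) dtau and its sum."""
    t0 = state_at_t0.time
    if t < t0:
        raise ValueError("t must be >= t0")
    nq = config.quadrature_points
    cm = model.compiled()
    abar = np.zeros_like(cm.pref)
    if t == t0 or cm.pref.shape[1] == 0:
        return abar, 0.0
    taus = np.linspace(t0, t, nq)
    w = np.full(nq, (t - t0) / (nq - 1))
    w[0] *= 0.5
    w[-1] *= 0.5
    for tau, wq in zip(taus, w):
        X = _displaced_counts(model, state_at_t0, flux_solutions, tau)
        abar += wq * _propensity_matrix(model, X)
    return abar, float(abar.sum())


def survival_probability(model, state_at_t0, flux_solutions, t, config) -> float:
    """P_R(t) = exp(-sum abar): probability of no reaction in (t0, t]."""
    _, tot = integrated_propensities(model, state_at_t0, flux_solutions, t, config)
    return float(np.exp(-tot))


def draw_next_reaction_time(
    model,
    state_at_t0,
    flux_solutions,
    r1: float,
    config: HybridConfig,
    max_dt: float = math.inf,
) -> tuple[float, bool]:
    """Solve P_R(t) = r1 for t; (t0 + cap, True) if no reaction by the cap.

    ``max_dt`` caps the step relative to t0 (``config.max_step`` also
    applies).  Bracket-doubling from dt = 1/a_tot(t0), then Brent refinement
    to a relative tolerance of ``config.root_tol``.
    """
    if not 0.0 < r1 < 1.0:
        raise ValueError("r1 must lie in (0, 1)")
    t0 = state_at_t0.time
    cap = min(config.max_step, max_dt)
    target = -math.log(r1)

    def cum(dt: float) -> float:
        _, tot = integrated_propensities(
            model, state_at_t0, flux_solutions, t0 + dt, config
        )
        return tot

    if not np.isfinite(cap):
        raise ValueError("draw_next_reaction_time needs a finite max_step/horizon")
    G_cap = cum(cap)
    if G_cap < target:
        return t0 + cap, True
    a0 = float(_propensity_matrix(model, state_at_t0.counts.astype(float)).sum())
    lo = 0.0
    hi = cap
    if a0 > 0 and 1.0 / a0 < cap:
        hi = 1.0 / a0
        while cum(hi) < target:
            lo = hi
            hi = min(2 * hi, cap)
            if hi == cap:
                break
    dt = scipy.optimize.brentq(
        lambda d: cum(d) - target, lo, hi,
        rtol=max(config.root_tol, 1e-12), xtol=1e-300,
    )
    return t0 + dt, False


def adaptive_cutoff(
    flux_solution: FluxSolution,
    lam: float,
    t: float,
    config: HybridConfig,
    mode: str = "monotone",
    xcol: np.ndarray | None = None,
    n_cols: int | None = None,
) -> RegionSplit:
    """Split the domain by the expected jump counts Lambda*phi(t).

    monotone: the SSA region starts at the smallest column kg whose leftward
    or rightward expected jump count drops to T_A.  central_peak: the
    Gaussian region is the largest interval around the flux peak where the
    counts stay above T_A.  In 2-D the rule is applied to the x-direction
    fluxes aggregated (summed) over each column of compartments.
    """
    ode = flux_solution.ode
    src, tgt = ode.index.src, ode.index.tgt
    if xcol is None:
        xcol = np.arange(ode.c0.size)
    if n_cols is None:
        n_cols = int(xcol.max()) + 1
    name = ode.species
    if mode == "ssa":
        return RegionSplit(name, (1, 0), n_cols)
    if mode == "none":
        return RegionSplit(name, (0, n_cols - 1), n_cols)

    nphi = lam * flux_solution.phi(t)
    colL = np.zeros(n_cols)
    colR = np.zeros(n_cols)
    cs, ct = xcol[src], xcol[tgt]
    np.add.at(colL, cs[ct == cs - 1], nphi[ct == cs - 1])
    np.add.at(colR, cs[ct == cs + 1], nphi[ct == cs + 1])
    g1, g2 = split_from_column_fluxes(colL, colR, config.ta, mode)
    return RegionSplit(name, (g1, g2), n_cols)


def split_from_column_fluxes(
    colL: np.ndarray, colR: np.ndarray, ta: float, mode: str
) -> tuple[int, int]:
    """Gaussian column range [g1, g2] from expected jump counts Lambda*phi.

    ``colL[k]`` / ``colR[k]`` are the leftward/rightward expected jump counts
    out of column k (0-based); boundary columns lack one direction and are
    judged on the other alone.  Returns an inclusive 0-based range; (1, 0)
    means SSA everywhere.
    """
    n_cols = len(colL)

    def below(ix: int) -> bool:
        return (ix > 0 and colL[ix] <= ta) or (
            ix < n_cols - 1 and colR[ix] <= ta
        )

    if mode == "monotone":
        for ix in range(n_cols):
            if below(ix):
                return (0, ix - 1)
        return (0, n_cols - 1)
    if mode == "central_peak":
        peak = int(np.argmax(np.maximum(colL, colR)))
        if below(peak):
            return (1, 0)
        g1 = peak
        while g1 > 0 and not below(g1 - 1):
            g1 -= 1
        g2 = peak
        while g2 < n_cols - 1 and not below(g2 + 1):
            g2 += 1
        return (g1, g2)
    raise ValueError(f"unknown adaptivity mode {mode!r}")


def select_reaction(abar: np.ndarray, r2: float) -> tuple[int, int]:
    """Smallest (compartment, reaction) in compartment-major order whose
    cumulative integrated propensity reaches r2 * sum(abar)."""
    if not 0.0 < r2 < 1.0:
        raise ValueError("r2 must lie in (0, 1)")
    flat = np.asarray(abar).ravel()
    tot = flat.sum()
    if tot <= 0:
        raise ValueError("total integrated propensity is zero; use the "
                         "no-reaction path")
    idx = int(np.searchsorted(np.cumsum(flat), r2 * tot, side="left"))
    idx = min(idx, flat.size - 1)
    return divmod(idx, abar.shape[1])


# ---------------------------------------------------------------------------
# reference one-step implementation (edge-space sampling, paper-literal)
# ---------------------------------------------------------------------------


def hybrid_step(
    model: ReactionDiffusionModel,
    state: SystemState,
    config: HybridConfig,
    rng: np.random.Generator,
    horizon: float = math.inf,
) -> tuple[SystemState, StepInfo]:
    """One hybrid step from ``state``; returns the new state and step info."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cm = model.compiled()
    t0 = state.time
    cap = min(config.max_step, horizon - t0)
    if not np.isfinite(cap) or cap <= 0:
        raise ValueError("hybrid_step needs a positive finite step cap "
                         "(max_step or horizon)")

    flux_solutions: dict[str, FluxSolution] = {}
    odes = {}
    for sp in model.diffusive_species():
        if model.n_compartments > 1:
            ode = build_flux_ode(model, sp, state)
            odes[sp] = ode
            flux_solutions[sp] = solve_mean_flux(ode, t0)

    no_rx = True
    t = t0 + cap
    if len(model.reactions):
        r1 = 1.0 - rng.random()
        if r1 < 1.0:
            t, no_rx = draw_next_reaction_time(
                model, state, flux_solutions, r1, config, max_dt=cap
            )
    dt = t - t0

    X = state.counts.astype(float)
    splits: dict[str, RegionSplit] = {}
    clamp_loss = 0.0
    for sp, ode in odes.items():
        i = model.species_index(sp)
        lam = cm.lam[i]
        sol = solve_mean_flux(ode, t)
        split = adaptive_cutoff(sol, lam, t, config, mode=config.mode_for(sp),
                                xcol=cm.xcol, n_cols=cm.Kx)
        splits[sp] = split
        gmask = split.gaussian_mask(cm.xcol)
        work = SystemState(np.round(X).astype(np.int64), t0)

        if split.is_empty:
            X[:, i] = ssa_diffusion_only(model, sp, np.arange(cm.K), t0, t,
                                         work, rng)
            continue
        if not split.is_full:
            region = np.where(~gmask)[0]
            X[:, i] = ssa_diffusion_only(model, sp, region, t0, t, work, rng)

        src, tgt = ode.index.src, ode.index.tgt
        in_g_src = gmask[src]
        in_g_tgt = gmask[tgt]
        eg = np.where(in_g_src)[0]                      # sampled edges
        det = np.where(in_g_tgt & ~in_g_src)[0]         # mean influx edges
        rho = flux_covariance(ode, sol, t).rho
        rho_s = rho[np.ix_(eg, eg)]
        xi = sample_flux_noise(rho_s, rng)
        n_eg = lam * sol.phi_at[eg] + math.sqrt(lam) * xi
        x = X[:, i].copy()
        np.add.at(x, src[eg], -n_eg)
        np.add.at(x, tgt[eg], n_eg)
        n_det = lam * sol.phi_at[det]
        np.add.at(x, src[det], -n_det)
        np.add.at(x, tgt[det], n_det)
        neg = x < 0
        clamp_loss += float(-x[neg].sum())
        x = np.where(neg, 0.0, np.floor(x + 0.5))
        X[:, i] = x

    reaction = None
    if not no_rx:
        abar, tot = integrated_propensities(model, state, flux_solutions, t, config)
        if tot > 0:
            reaction = select_reaction(abar, 1.0 - rng.random())
            q, r = reaction
            X[q] += cm.net[r]
            neg = X[q] < 0
            clamp_loss += float(-X[q][neg].sum())
            X[q][neg] = 0.0

    new_state = SystemState(np.round(X).astype(np.int64), t)
    return new_state, StepInfo(t=t, dt=dt, no_reaction=no_rx, reaction=reaction,
                               splits=splits, clamp_loss=clamp_loss)


# ---------------------------------------------------------------------------
# full trajectories
# ---------------------------------------------------------------------------


def _mode_codes(model: ReactionDiffusionModel, config: HybridConfig) -> np.ndarray:
    cm = model.compiled()
    codes = []
    for i in cm.dspec:
        codes.append(ADAPTIVITY_MODES[config.mode_for(model.species[i].name)])
    return np.asarray(codes, dtype=np.int64)


def hybrid_simulate(
    model: ReactionDiffusionModel,
    initial: SystemState,
    t_end: float,
    sample_times: Sequence[float],
    config: HybridConfig | None = None,
    rng=None,
    engine: str = "compiled",
) -> Trajectory:
    """Hybrid-method trajectory sampled at ``sample_times``.

    Steps never straddle a sample time: the remaining horizon to the next
    sample caps each step (a capped step is a no-reaction diffusion update),
    so snapshots are exact states at the requested times.
    """
    config = config or HybridConfig()
    ts = _check_sampling(initial, t_end, sample_times)
    cm = model.compiled()

    if engine == "reference":
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        state = initial.copy()
        out = np.empty((ts.size, cm.K, cm.S), dtype=np.int64)
        diagnostics = {"steps": 0, "no_reaction_steps": 0, "clamp_loss": 0.0}
        for si, tcap in enumerate(ts):
            while state.time < tcap * (1 - 1e-12) - 1e-12:
                state, info = hybrid_step(model, state, config, rng, horizon=tcap)
                diagnostics["steps"] += 1
                diagnostics["no_reaction_steps"] += int(info.no_reaction)
                diagnostics["clamp_loss"] += info.clamp_loss
            out[si] = state.counts
        return Trajectory(ts, out, rng_seed=None, method="hybrid",
                          clamp_loss=diagnostics["clamp_loss"],
                          diagnostics=diagnostics)

    if engine != "compiled":
        raise ValueError(f"unknown engine {engine!r}")

    seed = _resolve_seed(rng)
    lam0, U = cm.eig()
    nd = cm.dspec.size
    trace = int(config.trace_steps)
    kg_trace = np.full((trace, max(nd, 1), 2), -1.0)
    dt_trace = np.full(trace, np.nan)
    X = initial.counts.astype(np.float64)
    _kernels.seed_rng(seed)
    out, diag = _kernels.hybrid_kernel(
        X, initial.time, ts,
        cm.stoich, cm.net, cm.pref, cm.lam,
        cm.src, cm.tgt, U, lam0, cm.xcol, cm.Kx,
        cm.nbr, cm.nbr_cnt,
        cm.dspec, cm.jump_rate[cm.dspec], _mode_codes(model, config),
        float(config.ta), int(config.quadrature_points),
        float(config.root_tol),
        float(config.max_step) if np.isfinite(config.max_step) else 1e300,
        float(config.psd_repair_tol),
        kg_trace, dt_trace,
    )
    diagnostics = {
        "steps": int(diag[_kernels.DIAG_STEPS]),
        "reactions": int(diag[_kernels.DIAG_REACTIONS]),
        "no_reaction_steps": int(diag[_kernels.DIAG_NOREACT]),
        "clamp_loss": float(diag[_kernels.DIAG_CLAMP_LOSS]),
        "rounding_net": float(diag[_kernels.DIAG_ROUND_NET]),
        "ssa_fallback_steps": int(diag[_kernels.DIAG_SSA_FALLBACK]),
        "psd_repairs": int(diag[_kernels.DIAG_PSD_REPAIR]),
    }
    if trace:
        diagnostics["kg_trace"] = kg_trace
        diagnostics["dt_trace"] = dt_trace
    return Trajectory(ts, np.round(out), rng_seed=seed, method="hybrid",
                      clamp_loss=diagnostics["clamp_loss"],
                      diagnostics=diagnostics)
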