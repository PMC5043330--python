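"""Continuous Gaussian approximation of diffusive jump fluxes.

Over a reaction-free window [t0, t], the number of diffusive jumps fired by
each directed channel e (source compartment src(e)) is approximated as

    n_e = Lambda * phi_e(t) + sqrt(Lambda) * xi_e,

the standard system-size scaling: ``phi`` is the deterministic cumulative
flux per unit concentration and ``xi`` a zero-mean Gaussian fluctuation.
The mean fluxes solve the linear ODE

    dPhi/dt = A Phi + C,      Phi(t0) = 0,

where A couples each flux to the fluxes entering/leaving its source
compartment and C = (D/h^2) c0.  Equivalently dphi_e/dt = (D/h^2) m_src(e)(t)
with m(t) the deterministic compartment concentrations, which is how the
solver evaluates it (via the symmetric lattice Laplacian's eigenbasis).  The
fluctuation covariance rho(t) solves the Lyapunov ODE

    drho/dt = A rho + rho A' + B(t),    rho(t0) = 0,   B = diag(dPhi/dt),

whose integral form rho = int Y(t) Y^-1(tau) B(tau) Y^-1(tau)' Y(t)' dtau
(Y = exp(A .)) is retained as an independent cross-check route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.integrate
import scipy.linalg

from .model import (
    ModelSpecificationError,
    ReactionDiffusionModel,
    SystemState,
    canonical_edges,
)

__all__ = [
    "FluxIndex",
    "FluxODE",
    "FluxSolution",
    "CovarianceResult",
    "build_flux_ode",
    "solve_mean_flux",
    "flux_covariance",
    "sample_flux_noise",
    "jump_counts_from_flux",
]


@dataclass(frozen=True)
class FluxIndex:
    """Canonical directed-edge ordering for one species' fluxes.

    In 1-D the order is (xi_1R, xi_2L, xi_2R, ..., xi_KL): the k -> k-1
    ("L") flux of compartment k (1-based) sits at 1-based position 2k-2 and
    the k -> k+1 ("R") flux at 2k-1.
    """

    species: str
    src: np.ndarray
    tgt: np.ndarray

    @property
    def n_edges(self) -> int:
        return self.src.size

    def position(self, compartment: int, direction: str) -> int:
        """0-based edge index of the (1-based compartment, 'L'/'R') channel."""
        k = compartment
        if direction == "L":
            if k < 2:
                raise ValueError("compartment 1 has no leftward channel")
            return 2 * k - 3  # 1-based position 2k-2
        if direction == "R":
            return 2 * k - 2  # 1-based position 2k-1
        raise ValueError("direction must be 'L' or 'R'")

    def channel(self, position: int) -> tuple[int, str]:
        """Inverse of :meth:`position` (1-based compartment, direction)."""
        s, t = int(self.src[position]), int(self.tgt[position])
        return (s + 1, "L" if t == s - 1 else "R")


@dataclass
class FluxODE:
    """dPhi/dt = A Phi + C with Phi(t0) = 0, for one diffusive species."""

    species: str
    A: np.ndarray          # (E, E)
    C: np.ndarray          # (E,)
    rate: float            # D / h^2
    lam: float             # Lambda of the species
    c0: np.ndarray         # (K,) initial concentrations counts/Lambda
    t0: float
    index: FluxIndex
    _eig: tuple = field(default=None, repr=False)

    @property
    def n_edges(self) -> int:
        return self.C.size

    def eig(self):
        """(lam0, U) of the unscaled compartment Laplacian (cached)."""
        if self._eig is None:
            K = self.c0.size
            L0 = np.zeros((K, K))
            for s, t in zip(self.index.src, self.index.tgt):
                L0[t, s] += 1.0
                L0[s, s] -= 1.0
            lam0, U = scipy.linalg.eigh(L0)
            self._eig = (lam0, U)
        return self._eig

    def mean_concentration(self, t: float) -> np.ndarray:
        """Deterministic m(t) = exp(L (t - t0)) c0 on the compartments."""
        lam0, U = self.eig()
        chat = U.T @ self.c0
        return U @ (np.exp(self.rate * lam0 * (t - self.t0)) * chat)


@dataclass
class FluxSolution:
    """Evaluator for Phi(t) and B(t) = diag(dPhi/dt) over [t0, inf)."""

    ode: FluxODE
    t: float               # time at which phi_at/b_at were evaluated
    phi_at: np.ndarray     # (E,) cumulative mean flux at t
    b_at: np.ndarray       # (E,) dPhi/dt at t

    @property
    def t0(self) -> float:
        return self.ode.t0

    def phi(self, t: float) -> np.ndarray:
        if t < self.t0:
            raise ValueError("t must be >= t0")
        lam0, U = self.ode.eig()
        chat = U.T @ self.ode.c0
        dt = t - self.t0
        z = self.ode.rate * lam0
        g = np.where(np.abs(z) < 1e-13, dt, np.expm1(z * dt) / np.where(z == 0, 1.0, z))
        J = U @ (g * chat)  # integral of m over [t0, t]
        return self.ode.rate * J[self.ode.index.src]

    def dphi(self, t: float) -> np.ndarray:
        m = self.ode.mean_concentration(t)
        return self.ode.rate * m[self.ode.index.src]

    def b(self, t: float) -> np.ndarray:
        return np.clip(self.dphi(t), 0.0, None)

    def net_mean_flux(self, t: float) -> np.ndarray:
        """(N Phi)(t): per-compartment net cumulative flux (concentration)."""
        phi = self.phi(t)
        K = self.ode.c0.size
        out = np.zeros(K)
        np.add.at(out, self.ode.index.tgt, phi)
        np.add.at(out, self.ode.index.src, -phi)
        return out


@dataclass
class CovarianceResult:
    """Covariance rho(t) of the flux fluctuations Xi over the edge index."""

    rho: np.ndarray
    t0: float
    t: float
    species: str = ""

    def submatrix(self, keep: np.ndarray) -> "CovarianceResult":
        keep = np.asarray(keep, dtype=int)
        return CovarianceResult(self.rho[np.ix_(keep, keep)], self.t0, self.t,
                                self.species)

    def restrict_below(self, kg: int) -> "CovarianceResult":
        """Remove 1-based rows/cols 2 kg - 2 ... 2K - 2: keep the first
        2 kg - 3 fluxes (those sourced in compartments 1..kg-1)."""
        return self.submatrix(np.arange(max(2 * kg - 3, 0)))


def build_flux_ode(
    model: ReactionDiffusionModel, species: str, state_at_t0: SystemState
) -> FluxODE:
    """Assemble the mean-flux ODE for one diffusive species at a state."""
    spec = model.species_spec(species)
    if spec.diffusion_coefficient <= 0:
        raise ModelSpecificationError(f"species {species!r} is not diffusive")
    if model.n_compartments < 2:
        raise ModelSpecificationError("flux ODE needs at least 2 compartments")
    if np.any(state_at_t0.counts < 0):
        raise ValueError("counts must be non-negative")
    src, tgt = canonical_edges(model.grid)
    r = spec.diffusion_coefficient / model.grid.spacing**2
    i = model.species_index(species)
    c0 = state_at_t0.counts[:, i].astype(float) / spec.lambda_scale
    E = src.size
    A = np.zeros((E, E))
    for e in range(E):
        for f in range(E):
            if tgt[f] == src[e]:
                A[e, f] += r
            if src[f] == src[e]:
                A[e, f] -= r
    C = r * c0[src]
    return FluxODE(species=species, A=A, C=C, rate=r, lam=spec.lambda_scale,
                   c0=c0, t0=state_at_t0.time,
                   index=FluxIndex(species=species, src=src, tgt=tgt))


def solve_mean_flux(ode: FluxODE, t: float) -> FluxSolution:
    """Solve Phi(t) with Phi(t0) = 0; exact via the Laplacian eigenbasis."""
    if t < ode.t0:
        raise ValueError("t must be >= t0")
    sol = FluxSolution(ode=ode, t=t, phi_at=np.zeros(ode.n_edges),
                       b_at=np.zeros(ode.n_edges))
    sol.phi_at = sol.phi(t)
    sol.b_at = sol.b(t)
    return sol


def flux_covariance(
    ode: FluxODE,
    solution: FluxSolution,
    t: float,
    method: str = "lyapunov",
    quad_nodes: int = 64,
    rtol: float = 1e-6,
) -> CovarianceResult:
    """Covariance rho(t) of the flux fluctuations.

    ``method='lyapunov'`` integrates drho/dt = A rho + rho A' + B(t) with an
    adaptive ODE solver; ``method='quadrature'`` evaluates the explicit
    propagator integral with >= ``quad_nodes`` trapezoid nodes and
    scipy.linalg.expm, kept as an independent cross-check.
    """
    if t < ode.t0:
        raise ValueError("t must be >= t0")
    E = ode.n_edges
    if t == ode.t0 or not np.any(ode.C):
        return CovarianceResult(np.zeros((E, E)), ode.t0, t, ode.species)

    if method == "lyapunov":
        A = ode.A

        def rhs(tau, y):
            rho = y.reshape(E, E)
            drho = A @ rho + rho @ A.T + np.diag(solution.b(tau))
            return drho.ravel()

        scale = float(np.max(ode.C)) * (t - ode.t0) + 1e-30
        res = scipy.integrate.solve_ivp(
            rhs, (ode.t0, t), np.zeros(E * E), method="RK45",
            rtol=rtol, atol=1e-10 * scale,
            first_step=min((t - ode.t0) / 8, 0.1 / max(abs(ode.A).max(), 1e-12)),
        )
        if not res.success:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"Lyapunov integration failed: {res.message}; "
                f"cond(A)~{np.linalg.cond(ode.A):.2e}"
            )
        rho = res.y[:, -1].reshape(E, E)
    elif method == "quadrature":
        n = max(int(quad_nodes), 64)
        h = (t - ode.t0) / n
        Mh = scipy.linalg.expm(ode.A * h)
        rho = np.zeros((E, E))
        P = np.eye(E)  # exp(A * (t - tau_j)) built backwards from tau = t
        for j in range(n, -1, -1):
            w = 0.5 if j in (0, n) else 1.0
            B = np.diag(solution.b(ode.t0 + j * h))
            rho += w * (P @ B @ P.T)
            P = P @ Mh
        rho *= h
    else:
        raise ValueError(f"unknown method {method!r}")

    rho = 0.5 * (rho + rho.T)
    return CovarianceResult(rho, ode.t0, t, ode.species)


def sample_flux_noise(cov, rng, size: int | None = None) -> np.ndarray:
    """Draw Xi ~ N(0, rho), repairing tiny negative eigenvalues.

    Eigenvalues in [-1e-10 * ||rho||, 0) are clipped to zero; anything more
    negative raises, reporting the offending eigenvalue.
    """
    rho = cov.rho if isinstance(cov, CovarianceResult) else np.asarray(cov)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    E = rho.shape[0]
    if E == 0:
        return np.zeros(0 if size is None else (size, 0))
    evals, evecs = np.linalg.eigh(rho)
    norm = max(float(evals[-1]), 0.0)
    tol = 1e-10 * norm + 1e-300
    if evals[0] < -tol:
        raise FloatingPointError(
            f"covariance is indefinite: eigenvalue {evals[0]:.3e} "
            f"(tolerance {-tol:.3e})"
        )
    evals = np.clip(evals, 0.0, None)
    shape = (E,) if size is None else (size, E)
    z = rng.standard_normal(shape)
    return z @ (evecs * np.sqrt(evals)).T if size else (evecs * np.sqrt(evals)) @ z


def jump_counts_from_flux(solution, xi: np.ndarray, lam: float) -> np.ndarray:
    """n_e = Lambda phi_e + sqrt(Lambda) xi_e (real-valued at this stage;
    rounding/clamping is the hybrid engine's job)."""
    phi = solution.phi_at if isinstance(solution, FluxSolution) else np.asarray(solution)
    xi = np.asarray(xi)
    if phi.shape != xi.shape[-phi.ndim:]:
        raise ValueError("phi and xi shapes disagree")
    return lam * phi + np.sqrt(lam) * xi
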