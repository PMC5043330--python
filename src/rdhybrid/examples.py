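"""Builders for the benchmark morphogen and Turing systems.

The examples are 1-D/2-D morphogen-gradient models of the Drosophila
wing-disc type (compartment width 2 um matching the cell size) and a
normalized activator-substrate Turing system:

* ``example1``        - morphogen M produced on [0, x_pro], linear decay.
* ``example2``        - morphogen-receptor system (M + R <-> W, receptor
                        turnover); morphogen is lost only through binding.
* ``example3``        - adds non-signalling receptors N and a second
                        diffusive species, the complex C ("bucket brigade").
* ``example4_2d``     - example1 on a 50 x 5 compartment strip.
* ``example5_central``- example1 with a central production region
                        (non-monotone profile; central-peak adaptivity).
* ``example6_turing`` - activator-substrate Turing system (fast substrate
                        diffusion handled by the Gaussian approximation,
                        slow activator diffusion by the SSA).
* ``pure_diffusion``, ``birth_death`` - minimal fixtures.

Defaults reproduce the published parameter set of the morphogen examples
(see PARAMETERS); every builder accepts keyword overrides.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import scipy.integrate

from .hybrid import HybridConfig
from .model import (
    CompartmentGrid,
    ModelSpecificationError,
    ReactionDiffusionModel,
    ReactionSpec,
    SpeciesSpec,
    SystemState,
)

__all__ = [
    "PARAMETERS",
    "EXAMPLE_NAMES",
    "build_example",
    "default_config",
    "deterministic_reference",
    "fixture_generator",
]

#: Published parameter set for the morphogen examples (units: um, s, uM).
PARAMETERS: Mapping[str, float] = {
    "v_M": 1e-4,      # morphogen production rate, uM/s
    "v_R": 1e-4,      # receptor production rate, uM/s
    "v_N": 2e-4,      # non-signalling receptor production rate, uM/s
    "d_M": 1e-2,      # morphogen degradation, 1/s
    "d_R": 1e-4,      # receptor degradation, 1/s
    "d_N": 1e-4,      # non-signalling receptor degradation, 1/s
    "d_W": 1e-4,      # complex W degradation, 1/s
    "d_C": 1e-4,      # complex C degradation, 1/s
    "alpha1": 5e-2,   # M + R binding, 1/(uM s)
    "beta1": 5e-4,    # W dissociation, 1/s
    "alpha2": 5e-2,   # M + N binding, 1/(uM s)
    "beta2": 5e-4,    # C dissociation, 1/s
    "lam_M": 1.8e4,   # morphogens per uM per compartment
    "lam_R": 2e2,     # receptors (and complexes) per uM per compartment
    "x_pro": 14.0,    # production region size, um
}

EXAMPLE_NAMES = (
    "example1",
    "example2",
    "example3",
    "example4_2d",
    "example5_central",
    "example6_turing",
    "pure_diffusion",
    "birth_death",
)


def _production_profile(grid: CompartmentGrid, lo: float, hi: float) -> np.ndarray:
    """1.0 for compartments whose centre x lies in [lo, hi], else 0."""
    cx = grid.centers_x()
    return ((cx >= lo) & (cx <= hi)).astype(float)


def _initial(model: ReactionDiffusionModel, conc: Mapping[str, np.ndarray | float]):
    K, S = model.n_compartments, model.n_species
    counts = np.zeros((K, S), dtype=np.int64)
    for sp, c in conc.items():
        i = model.species_index(sp)
        lam = model.species[i].lambda_scale
        counts[:, i] = np.round(lam * np.broadcast_to(np.asarray(c, float), (K,)))
    return SystemState(counts, 0.0)


def build_example(name: str, **overrides):
    """Build a named example; returns ``(model, initial_state)``.

    Overrides: any PARAMETERS key, plus ``K``/``extent``, ``h``, ``D_M``,
    ``D_C``, Turing parameters (``D_A``, ``D_S``, ``alpha``, ``beta``,
    ``rho_A``, ``rho_S``, ``lam``), and fixture-specific keywords.
    """
    p = dict(PARAMETERS)
    for key in list(overrides):
        if key in p:
            p[key] = overrides.pop(key)

    if name == "example1" or name == "example5_central":
        K = int(overrides.pop("K", 100))
        h = float(overrides.pop("h", 2.0))
        D_M = float(overrides.pop("D_M", 40.0))
        if name == "example1":
            lo, hi = 0.0, p["x_pro"]
        else:
            centre = K * h / 2.0
            lo, hi = centre - 6.0, centre + 6.0
        lo = float(overrides.pop("prod_lo", lo))
        hi = float(overrides.pop("prod_hi", hi))
        _reject_unused(name, overrides)
        grid = CompartmentGrid(extent=(K,), spacing=h)
        profile = _production_profile(grid, lo, hi)
        model = ReactionDiffusionModel(
            species=[SpeciesSpec("M", D_M, p["lam_M"])],
            grid=grid,
            reactions=[
                ReactionSpec({}, {"M": 1}, p["v_M"], profile, name="production"),
                ReactionSpec({"M": 1}, {}, p["d_M"], name="degradation"),
            ],
            name=name,
        )
        return model, _initial(model, {"M": profile * p["v_M"] / p["d_M"]})

    if name in ("example2", "example3"):
        K = int(overrides.pop("K", 100))
        h = float(overrides.pop("h", 2.0))
        D_M = float(overrides.pop("D_M", 5.0))
        D_C = float(overrides.pop("D_C", 5.0))
        _reject_unused(name, overrides)
        grid = CompartmentGrid(extent=(K,), spacing=h)
        profile = _production_profile(grid, 0.0, p["x_pro"])
        species = [
            SpeciesSpec("M", D_M, p["lam_M"]),
            SpeciesSpec("R", 0.0, p["lam_R"]),
            SpeciesSpec("W", 0.0, p["lam_R"]),
        ]
        reactions = [
            ReactionSpec({}, {"M": 1}, p["v_M"], profile, name="M production"),
            ReactionSpec({"M": 1, "R": 1}, {"W": 1}, p["alpha1"], name="binding"),
            ReactionSpec({"W": 1}, {"M": 1, "R": 1}, p["beta1"], name="dissociation"),
            ReactionSpec({}, {"R": 1}, p["v_R"], name="R production"),
            ReactionSpec({"R": 1}, {}, p["d_R"], name="R degradation"),
            ReactionSpec({"W": 1}, {}, p["d_W"], name="W degradation"),
        ]
        conc = {"M": profile * p["v_M"] / p["d_M"], "R": p["v_R"] / p["d_R"],
                "W": 0.0}
        if name == "example3":
            species += [
                SpeciesSpec("N", 0.0, p["lam_R"]),
                SpeciesSpec("C", D_C, p["lam_R"]),
            ]
            reactions += [
                ReactionSpec({}, {"N": 1}, p["v_N"], name="N production"),
                ReactionSpec({"N": 1}, {}, p["d_N"], name="N degradation"),
                ReactionSpec({"M": 1, "N": 1}, {"C": 1}, p["alpha2"],
                             name="N binding"),
                ReactionSpec({"C": 1}, {"M": 1, "N": 1}, p["beta2"],
                             name="C dissociation"),
                ReactionSpec({"C": 1}, {}, p["d_C"], name="C degradation"),
            ]
            conc.update({"N": p["v_N"] / p["d_N"], "C": 0.0})
        model = ReactionDiffusionModel(species, grid, reactions, name=name)
        return model, _initial(model, conc)

    if name == "example4_2d":
        kx = int(overrides.pop("Kx", 50))
        ky = int(overrides.pop("Ky", 5))
        h = float(overrides.pop("h", 2.0))
        D_M = float(overrides.pop("D_M", 40.0))
        _reject_unused(name, overrides)
        grid = CompartmentGrid(extent=(kx, ky), spacing=h)
        profile = _production_profile(grid, 0.0, p["x_pro"])
        model = ReactionDiffusionModel(
            species=[SpeciesSpec("M", D_M, p["lam_M"])],
            grid=grid,
            reactions=[
                ReactionSpec({}, {"M": 1}, p["v_M"], profile, name="production"),
                ReactionSpec({"M": 1}, {}, p["d_M"], name="degradation"),
            ],
            name=name,
        )
        return model, _initial(model, {"M": profile * p["v_M"] / p["d_M"]})

    if name == "example6_turing":
        K = int(overrides.pop("K", 50))
        h = float(overrides.pop("h", 10.0 / K))
        D_A = float(overrides.pop("D_A", 0.1))
        D_S = float(overrides.pop("D_S", 50.0))
        alpha = float(overrides.pop("alpha", 1.0))
        beta = float(overrides.pop("beta", 1.0))
        rho_A = float(overrides.pop("rho_A", 0.01))
        rho_S = float(overrides.pop("rho_S", 1.0))
        lam = float(overrides.pop("lam", 500.0))
        a0 = float(overrides.pop("A0", 1.01))
        _reject_unused(name, overrides)
        grid = CompartmentGrid(extent=(K,), spacing=h)
        model = ReactionDiffusionModel(
            species=[SpeciesSpec("A", D_A, lam), SpeciesSpec("S", D_S, lam)],
            grid=grid,
            reactions=[
                ReactionSpec({"S": 1, "A": 2}, {"A": 3}, alpha, name="autocatalysis"),
                ReactionSpec({"A": 1}, {}, beta, name="A degradation"),
                ReactionSpec({}, {"A": 1}, rho_A, name="A production"),
                ReactionSpec({}, {"S": 1}, rho_S, name="S production"),
            ],
            name=name,
        )
        return model, _initial(model, {"A": a0, "S": a0 ** -2})

    if name == "pure_diffusion":
        K = int(overrides.pop("K", 3))
        h = float(overrides.pop("h", 1.0))
        D = float(overrides.pop("D", 1.0))
        lam = float(overrides.pop("lam", 1e4))
        conc = overrides.pop("conc", None)
        extent = overrides.pop("extent", (K,))
        _reject_unused(name, overrides)
        grid = CompartmentGrid(extent=tuple(extent), spacing=h)
        model = ReactionDiffusionModel(
            species=[SpeciesSpec("X", D, lam)], grid=grid, reactions=[],
            name=name,
        )
        if conc is None:
            conc = np.zeros(grid.n_compartments)
            conc[0] = 1.0
        return model, _initial(model, {"X": conc})

    if name == "birth_death":
        K = int(overrides.pop("K", 1))
        h = float(overrides.pop("h", 1.0))
        D = float(overrides.pop("D", 0.0))
        lam = float(overrides.pop("lam", 1e3))
        v = float(overrides.pop("v", 1e-2))
        d = float(overrides.pop("d", 1e-1))
        conc = overrides.pop("conc", None)
        if conc is None:
            conc = v / d if d > 0 else 0.0
        _reject_unused(name, overrides)
        grid = CompartmentGrid(extent=(K,), spacing=h)
        model = ReactionDiffusionModel(
            species=[SpeciesSpec("X", D, lam)],
            grid=grid,
            reactions=[
                ReactionSpec({}, {"X": 1}, v, name="birth"),
                ReactionSpec({"X": 1}, {}, d, name="death"),
            ],
            name=name,
        )
        return model, _initial(model, {"X": conc})

    raise ModelSpecificationError(f"unknown example {name!r}")


def _reject_unused(name, overrides):
    if overrides:
        raise ModelSpecificationError(
            f"{name}: unknown overrides {sorted(overrides)}"
        )


def default_config(name: str, **kwargs) -> HybridConfig:
    """Recommended hybrid configuration per example."""
    if name == "example5_central":
        kwargs.setdefault("adaptivity_mode", "central_peak")
    elif name == "example6_turing":
        kwargs.setdefault("adaptivity_mode", {"S": "none", "A": "ssa"})
    else:
        kwargs.setdefault("adaptivity_mode", "monotone")
    return HybridConfig(**kwargs)


def deterministic_reference(
    model: ReactionDiffusionModel,
    t_end: float,
    times,
    initial: SystemState | None = None,
    initial_concentration: np.ndarray | None = None,
    rtol: float = 1e-8,
):
    """Method-of-lines solution of the macroscopic reaction-diffusion ODEs.

    Returns concentrations with shape (n_times, K, S).  The reaction terms
    are the printed mass-action PDE terms gamma * profile * prod c^s (no
    finite-size corrections), diffusion is (D/h^2) L0 c.
    """
    cm = model.compiled()
    K, S = cm.K, cm.S
    if initial_concentration is not None:
        c0 = np.asarray(initial_concentration, float).reshape(K, S)
    elif initial is not None:
        c0 = initial.counts / cm.lam[None, :]
    else:
        raise ValueError("provide initial or initial_concentration")
    L0 = cm.laplacian0()
    reactions = model.reactions

    def rhs(_t, y):
        c = y.reshape(K, S)
        dc = np.zeros_like(c)
        for rx in reactions:
            rate = np.full(K, rx.rate) if rx.profile is None else rx.rate * rx.profile
            for sp, s in rx.reactants.items():
                rate = rate * c[:, model.species_index(sp)] ** s
            for i in model._changed_species(rx):
                spn = model.species[i].name
                net = rx.products.get(spn, 0) - rx.reactants.get(spn, 0)
                dc[:, i] += net * rate
        for i in cm.dspec:
            dc[:, i] += cm.jump_rate[i] * (L0 @ c[:, i])
        return dc.ravel()

    times = np.atleast_1d(np.asarray(times, float))
    res = scipy.integrate.solve_ivp(
        rhs, (0.0, float(t_end)), c0.ravel(), t_eval=times,
        method="LSODA", rtol=rtol, atol=1e-12,
    )
    if not res.success:
        raise RuntimeError(f"deterministic integration failed: {res.message}")
    return res.y.T.reshape(times.size, K, S)


def fixture_generator(spec: Mapping | None = None, rng=None) -> ReactionDiffusionModel:
    """Random small well-formed model for property tests (seed-reproducible).

    ``spec`` keys (all optional): K (<= 6), n_species (<= 3), lam_range,
    rate_range, max_order (<= 3), p_diffusive.
    """
    spec = dict(spec or {})
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    K = int(spec.get("K", rng.integers(2, 7)))
    n_sp = int(spec.get("n_species", rng.integers(1, 4)))
    lam_lo, lam_hi = spec.get("lam_range", (50.0, 500.0))
    rate_lo, rate_hi = spec.get("rate_range", (1e-3, 1.0))
    max_order = int(spec.get("max_order", 3))
    p_diff = float(spec.get("p_diffusive", 0.7))
    base_lam = float(rng.uniform(lam_lo, lam_hi))
    species = []
    for i in range(n_sp):
        D = float(rng.uniform(0.5, 5.0)) if rng.random() < p_diff else 0.0
        # powers of two keep every Lambda ratio integral
        species.append(
            SpeciesSpec(f"S{i}", D, base_lam * 2 ** int(rng.integers(0, 3)))
        )
    grid = CompartmentGrid(extent=(K,), spacing=float(rng.uniform(0.5, 2.0)))
    names = [s.name for s in species]
    reactions = []
    for _ in range(int(rng.integers(1, 4))):
        order = int(rng.integers(0, max_order + 1))
        reactants: dict[str, int] = {}
        for _ in range(order):
            sp = names[rng.integers(0, n_sp)]
            reactants[sp] = reactants.get(sp, 0) + 1
        products: dict[str, int] = {}
        for _ in range(int(rng.integers(0 if reactants else 1, 3))):
            sp = names[rng.integers(0, n_sp)]
            products[sp] = products.get(sp, 0) + 1
        if not reactants and not products:
            products[names[0]] = 1
        profile = None
        if rng.random() < 0.3:
            profile = rng.uniform(0.0, 1.0, K)
        reactions.append(
            ReactionSpec(reactants, products, float(rng.uniform(rate_lo, rate_hi)),
                         profile)
        )
    return ReactionDiffusionModel(species, grid, reactions, name="fixture")
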