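"""Data model for compartmental reaction-diffusion systems.

A spatial domain is partitioned into K identical compartments of width ``h``
(a 1-D chain or a 2-D rectangular lattice).  Molecules are well mixed inside a
compartment; they react only with molecules in the same compartment and hop to
nearest-neighbour compartments at the per-molecule rate D/h^2 (diffusion as a
first-order jump reaction, reflective/no-flux boundaries).  Copy numbers relate
to macroscopic concentrations through the per-species scale ``lambda_scale``
(Lambda), the number of molecules per unit concentration per compartment.

Stochastic mass-action convention
---------------------------------
Reactions are specified with *macroscopic* rate constants (concentration
units).  The propensity of reaction ``j`` in compartment ``k`` is

    a_kj = Lambda_ref * gamma_j * profile_j(k) * prod_i ff(X_ki, s^r_ij) / Lambda_i^{s^r_ij}

where ``ff(x, s) = x (x-1) ... (x-s+1)`` is the falling factorial and
``Lambda_ref`` is the smallest ``lambda_scale`` among the species whose copy
number the reaction changes.  One firing changes species ``i`` by
``(s^p_ij - s^r_ij) * Lambda_i / Lambda_ref`` molecules (the ratio must be an
integer).  This is the unique integer-preserving bookkeeping for which the
large-Lambda mean of every species reproduces the deterministic mass-action
PDE term exactly, including when reacting species carry different
``lambda_scale`` values.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SpeciesSpec",
    "CompartmentGrid",
    "ReactionSpec",
    "ReactionDiffusionModel",
    "SystemState",
    "JumpChannel",
    "ModelSpecificationError",
    "InvariantViolationError",
    "reaction_propensity",
    "reaction_state_change",
    "build_jump_channels",
    "model_from_config",
    "model_to_config",
    "initial_state_from_config",
    "load_model",
    "load_problem",
    "dump_model",
]


class ModelSpecificationError(ValueError):
    """Raised for ill-formed model specifications."""


class InvariantViolationError(ValueError):
    """Raised when a state or argument violates a structural invariant."""


@dataclass(frozen=True)
class SpeciesSpec:
    """One molecular species.

    Parameters
    ----------
    name : str
        Unique identifier.
    diffusion_coefficient : float
        D, in length^2/time; 0 for a non-diffusive species.
    lambda_scale : float
        Lambda, molecules per unit concentration per compartment.
    """

    name: str
    diffusion_coefficient: float = 0.0
    lambda_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.diffusion_coefficient < 0:
            raise ModelSpecificationError(
                f"species {self.name!r}: diffusion_coefficient must be >= 0"
            )
        if self.lambda_scale <= 0:
            raise ModelSpecificationError(
                f"species {self.name!r}: lambda_scale must be > 0"
            )


@dataclass(frozen=True)
class CompartmentGrid:
    """Uniform compartment lattice (1-D chain or 2-D rectangle).

    ``extent`` is ``(K,)`` or ``(Kx, Ky)``; ``spacing`` is the compartment
    width h.  Compartment 1 (1-based, as used in messages and documentation)
    covers the physical interval [0, h).  Internally compartments are
    flattened 0-based, x-major: flat = ix * Ky + iy.
    """

    extent: tuple[int, ...]
    spacing: float

    def __post_init__(self) -> None:
        ext = tuple(int(e) for e in self.extent)
        object.__setattr__(self, "extent", ext)
        if len(ext) not in (1, 2):
            raise ModelSpecificationError("grid must be 1-D or 2-D")
        if any(e < 1 for e in ext):
            raise ModelSpecificationError("grid extents must be >= 1")
        if self.spacing <= 0:
            raise ModelSpecificationError("grid spacing h must be > 0")

    @property
    def dimensionality(self) -> int:
        return len(self.extent)

    @property
    def n_compartments(self) -> int:
        return int(np.prod(self.extent))

    @property
    def shape(self) -> tuple[int, int]:
        """(Kx, Ky) with Ky = 1 in 1-D."""
        if len(self.extent) == 1:
            return (self.extent[0], 1)
        return (self.extent[0], self.extent[1])

    def x_index(self) -> np.ndarray:
        """0-based x (column) index of each flat compartment."""
        kx, ky = self.shape
        return np.repeat(np.arange(kx), ky)

    def centers_x(self) -> np.ndarray:
        """Physical x coordinate of each compartment centre."""
        return (self.x_index() + 0.5) * self.spacing


@dataclass(frozen=True)
class ReactionSpec:
    """One mass-action reaction channel.

    ``reactants`` and ``products`` map species names to non-negative integer
    stoichiometric coefficients.  ``rate`` is the macroscopic rate constant
    gamma (units set by the reaction order).  ``profile`` optionally scales
    the rate per compartment (flat array of length K, or None for uniform);
    it encodes spatially localised production such as V(x).
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate: float
    profile: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", dict(self.reactants))
        object.__setattr__(self, "products", dict(self.products))
        for side, coeffs in (("reactant", self.reactants), ("product", self.products)):
            for sp, s in coeffs.items():
                if int(s) != s or s < 0:
                    raise ModelSpecificationError(
                        f"{side} stoichiometry for {sp!r} must be a non-negative integer"
                    )
        if not self.reactants and not self.products:
            raise ModelSpecificationError(
                "reaction must have at least one reactant or product"
            )
        if self.rate < 0:
            raise ModelSpecificationError("reaction rate must be >= 0")
        if self.profile is not None:
            prof = np.asarray(self.profile, dtype=float)
            if np.any(prof < 0):
                raise ModelSpecificationError("spatial profile values must be >= 0")
            object.__setattr__(self, "profile", prof)

    def order(self) -> int:
        return int(sum(self.reactants.values()))


@dataclass(frozen=True)
class JumpChannel:
    """A directed diffusive jump between two neighbouring compartments."""

    species: str
    source: int  # 0-based flat compartment index
    target: int
    rate_constant: float  # D / h^2, per molecule


@dataclass
class SystemState:
    """Integer molecule counts per (compartment, species) at one time point."""

    counts: np.ndarray  # (K, S) int64
    time: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if not np.issubdtype(c.dtype, np.integer):
            if not np.all(c == np.round(c)):
                raise InvariantViolationError("counts must be integral")
            c = np.round(c).astype(np.int64)
        else:
            c = c.astype(np.int64, copy=False)
        if np.any(c < 0):
            raise InvariantViolationError("counts must be non-negative")
        self.counts = c

    def copy(self) -> "SystemState":
        return SystemState(self.counts.copy(), self.time)


class ReactionDiffusionModel:
    """Immutable description of species, reactions and the compartment grid."""

    def __init__(
        self,
        species: Sequence[SpeciesSpec],
        grid: CompartmentGrid,
        reactions: Sequence[ReactionSpec] = (),
        name: str = "model",
    ) -> None:
        self.species = tuple(species)
        self.grid = grid
        self.reactions = tuple(reactions)
        self.name = name
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ModelSpecificationError("species names must be unique")
        self._index = {n: i for i, n in enumerate(names)}
        for rx in self.reactions:
            for sp in list(rx.reactants) + list(rx.products):
                if sp not in self._index:
                    raise ModelSpecificationError(
                        f"reaction references undeclared species {sp!r}"
                    )
            if rx.profile is not None and rx.profile.shape != (grid.n_compartments,):
                raise ModelSpecificationError(
                    "spatial profile length must equal the number of compartments"
                )
        self._validate_lambda_ratios()
        self._compiled = None

    # -- basic queries ----------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_compartments(self) -> int:
        return self.grid.n_compartments

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ModelSpecificationError(f"unknown species {name!r}") from None

    def species_spec(self, name: str) -> SpeciesSpec:
        return self.species[self.species_index(name)]

    def lambda_array(self) -> np.ndarray:
        return np.array([s.lambda_scale for s in self.species])

    def diffusive_species(self) -> list[str]:
        return [s.name for s in self.species if s.diffusion_coefficient > 0]

    def jump_rate(self, name: str) -> float:
        sp = self.species_spec(name)
        return sp.diffusion_coefficient / self.grid.spacing**2

    # -- stoichiometry / Lambda bookkeeping -------------------------------

    def _changed_species(self, rx: ReactionSpec) -> list[int]:
        out = []
        for sp in set(rx.reactants) | set(rx.products):
            if rx.products.get(sp, 0) != rx.reactants.get(sp, 0):
                out.append(self.species_index(sp))
        return sorted(out)

    def reference_lambda(self, rx: ReactionSpec) -> float:
        changed = self._changed_species(rx)
        if changed:
            return min(self.species[i].lambda_scale for i in changed)
        involved = [self.species_index(sp) for sp in set(rx.reactants) | set(rx.products)]
        return min(self.species[i].lambda_scale for i in involved)

    def _validate_lambda_ratios(self) -> None:
        for rx in self.reactions:
            lam_ref = self.reference_lambda(rx)
            for i in self._changed_species(rx):
                ratio = self.species[i].lambda_scale / lam_ref
                if abs(ratio - round(ratio)) > 1e-9:
                    raise ModelSpecificationError(
                        f"reaction {rx.name or rx!r}: lambda ratio "
                        f"{self.species[i].name}/reference = {ratio} is not an integer; "
                        "per-event bookkeeping requires integral ratios"
                    )

    # -- serialization / identity -----------------------------------------

    def config_dict(self) -> dict:
        return model_to_config(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.config_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def compiled(self):
        """Cached array form used by the simulators (see :mod:`rdhybrid._compile`)."""
        if self._compiled is None:
            from . import _compile

            self._compiled = _compile.compile_model(self)
        return self._compiled

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ReactionDiffusionModel({self.name!r}, K={self.n_compartments}, "
            f"species={[s.name for s in self.species]}, "
            f"reactions={len(self.reactions)})"
        )


# -- operations ------------------------------------------------------------


def _check_compartment(model: ReactionDiffusionModel, compartment: int) -> None:
    if not 0 <= compartment < model.n_compartments:
        raise ModelSpecificationError(
            f"compartment index {compartment} out of range "
            f"(0..{model.n_compartments - 1}, i.e. 1..{model.n_compartments} 1-based)"
        )


def _falling_factorial(x: float, s: int) -> float:
    v = 1.0
    for m in range(s):
        f = x - m
        if f <= 0.0:
            return 0.0
        v *= f
    return v


def reaction_propensity(
    reaction: ReactionSpec,
    state: SystemState,
    compartment: int,
    model: ReactionDiffusionModel,
) -> float:
    """Event rate (events/time) of ``reaction`` in ``compartment`` at ``state``."""
    _check_compartment(model, compartment)
    if state.counts.shape != (model.n_compartments, model.n_species):
        raise InvariantViolationError(
            f"state shape {state.counts.shape} does not match model "
            f"({model.n_compartments}, {model.n_species})"
        )
    if np.any(state.counts[compartment] < 0):
        raise InvariantViolationError("negative counts")
    lam_ref = model.reference_lambda(reaction)
    prof = 1.0 if reaction.profile is None else float(reaction.profile[compartment])
    a = lam_ref * reaction.rate * prof
    for sp, s in reaction.reactants.items():
        if s == 0:
            continue
        i = model.species_index(sp)
        x = float(state.counts[compartment, i])
        a *= _falling_factorial(x, s) / model.species[i].lambda_scale**s
    return a


def reaction_state_change(
    reaction: ReactionSpec,
    compartment: int,
    model: ReactionDiffusionModel,
) -> np.ndarray:
    """Per-(compartment, species) integer increment caused by one firing."""
    _check_compartment(model, compartment)
    delta = np.zeros((model.n_compartments, model.n_species), dtype=np.int64)
    lam_ref = model.reference_lambda(reaction)
    for i in model._changed_species(reaction):
        sp = model.species[i].name
        net = reaction.products.get(sp, 0) - reaction.reactants.get(sp, 0)
        scale = int(round(model.species[i].lambda_scale / lam_ref))
        delta[compartment, i] = net * scale
    return delta


def canonical_edges(grid: CompartmentGrid) -> tuple[np.ndarray, np.ndarray]:
    """Directed nearest-neighbour lattice edges in canonical order.

    1-D: (1->2), (2->1), (2->3), (3->2), ..., (K-1->K), (K->K-1): the k->k-1
    ("leftward") channel sits at 1-based position 2k-2 and k->k+1 ("rightward")
    at 2k-1.  2-D: all x-direction edge pairs first (column by column), then
    the y-direction pairs; with Ky=1 this reduces to the 1-D order.
    """
    kx, ky = grid.shape
    src: list[int] = []
    tgt: list[int] = []

    def flat(ix: int, iy: int) -> int:
        return ix * ky + iy

    for ix in range(kx - 1):
        for iy in range(ky):
            src.append(flat(ix, iy))
            tgt.append(flat(ix + 1, iy))
            src.append(flat(ix + 1, iy))
            tgt.append(flat(ix, iy))
    for ix in range(kx):
        for iy in range(ky - 1):
            src.append(flat(ix, iy))
            tgt.append(flat(ix, iy + 1))
            src.append(flat(ix, iy + 1))
            tgt.append(flat(ix, iy))
    return np.asarray(src, dtype=np.int64), np.asarray(tgt, dtype=np.int64)


def build_jump_channels(
    model: ReactionDiffusionModel, species: str
) -> list[JumpChannel]:
    """Ordered diffusive jump channels of ``species`` (canonical edge order)."""
    spec = model.species_spec(species)
    if spec.diffusion_coefficient <= 0:
        raise ModelSpecificationError(f"species {species!r} is not diffusive")
    rate = spec.diffusion_coefficient / model.grid.spacing**2
    src, tgt = canonical_edges(model.grid)
    return [
        JumpChannel(species=species, source=int(s), target=int(t), rate_constant=rate)
        for s, t in zip(src, tgt)
    ]


# -- config file round trip ------------------------------------------------


def model_to_config(model: ReactionDiffusionModel) -> dict:
    grid = {
        "dimension": model.grid.dimensionality,
        "extents": list(model.grid.extent),
        "h": model.grid.spacing,
    }
    species = [
        {"name": s.name, "D": s.diffusion_coefficient, "lambda": s.lambda_scale}
        for s in model.species
    ]
    reactions = []
    for rx in model.reactions:
        entry: dict = {
            "rate": rx.rate,
            "reactants": dict(rx.reactants),
            "products": dict(rx.products),
        }
        if rx.name:
            entry["name"] = rx.name
        if rx.profile is not None:
            entry["profile"] = [float(v) for v in rx.profile]
        reactions.append(entry)
    return {"name": model.name, "grid": grid, "species": species, "reactions": reactions}


def model_from_config(cfg: Mapping) -> ReactionDiffusionModel:
    grid = CompartmentGrid(
        extent=tuple(cfg["grid"]["extents"]), spacing=float(cfg["grid"]["h"])
    )
    if "dimension" in cfg["grid"] and int(cfg["grid"]["dimension"]) != grid.dimensionality:
        raise ModelSpecificationError("grid dimension does not match extents")
    species = [
        SpeciesSpec(
            name=s["name"],
            diffusion_coefficient=float(s.get("D", 0.0)),
            lambda_scale=float(s.get("lambda", 1.0)),
        )
        for s in cfg["species"]
    ]
    reactions = []
    for r in cfg.get("reactions", []):
        profile = r.get("profile")
        reactions.append(
            ReactionSpec(
                reactants=r.get("reactants", {}),
                products=r.get("products", {}),
                rate=float(r["rate"]),
                profile=None if profile is None else np.asarray(profile, dtype=float),
                name=r.get("name", ""),
            )
        )
    return ReactionDiffusionModel(
        species=species, grid=grid, reactions=reactions, name=cfg.get("name", "model")
    )


def initial_state_from_config(model: ReactionDiffusionModel, cfg: Mapping) -> SystemState:
    """Initial counts from the optional ``initial_concentrations`` config key.

    Each species maps to a scalar concentration or a per-compartment table;
    counts are ``round(lambda_scale * concentration)``.  Species absent from
    the table start at zero.
    """
    counts = np.zeros((model.n_compartments, model.n_species), dtype=np.int64)
    for sp, conc in cfg.get("initial_concentrations", {}).items():
        i = model.species_index(sp)
        c = np.broadcast_to(np.asarray(conc, dtype=float),
                            (model.n_compartments,))
        counts[:, i] = np.round(model.species[i].lambda_scale * c)
    return SystemState(counts)


def load_problem(path) -> tuple[ReactionDiffusionModel, SystemState]:
    """Load a model config file together with its initial state."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    model = model_from_config(cfg)
    return model, initial_state_from_config(model, cfg)


def dump_model(model: ReactionDiffusionModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.config_dict(), fh, sort_keys=False)


def load_model(path) -> ReactionDiffusionModel:
    with open(path) as fh:
        return model_from_config(yaml.safe_load(fh))
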