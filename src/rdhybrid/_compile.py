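"""Array (structure-of-arrays) form of a model, shared by all simulators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .model import ReactionDiffusionModel, canonical_edges


@dataclass
class CompiledModel:
    """Flat numeric view of a :class:`ReactionDiffusionModel`.

    ``pref[k, r]`` is the event-rate prefactor
    ``Lambda_ref * gamma * profile(k) / prod_i Lambda_i**stoich[r, i]`` so the
    propensity is ``pref[k, r] * prod_i ff(X[k, i], stoich[r, i])``.
    ``net[r, i]`` is the (integer-valued) per-event copy-number change.
    ``U, lam0`` diagonalize the unscaled lattice Laplacian L0 (adjacency minus
    degree, reflective boundaries); the diffusion generator of species ``i`` is
    ``(D_i / h^2) * L0``.
    """

    K: int
    S: int
    Kx: int
    Ky: int
    h: float
    lam: np.ndarray          # (S,)
    jump_rate: np.ndarray    # (S,)  D/h^2
    stoich: np.ndarray       # (R, S) int64 reactant orders
    net: np.ndarray          # (R, S) float64, integer-valued
    pref: np.ndarray         # (K, R)
    src: np.ndarray          # (E,) canonical directed edges
    tgt: np.ndarray          # (E,)
    xcol: np.ndarray         # (K,) 0-based x index
    nbr: np.ndarray          # (K, maxdeg) neighbour flat indices (-1 padded)
    nbr_cnt: np.ndarray      # (K,)
    jumpw: np.ndarray        # (K, S) total per-molecule jump weight r*deg
    dspec: np.ndarray        # (nd,) diffusive species indices
    _eig: tuple | None = field(default=None, repr=False)

    @property
    def n_edges(self) -> int:
        return self.src.shape[0]

    def laplacian0(self) -> np.ndarray:
        """Unscaled lattice Laplacian L0 (K x K, symmetric, reflective)."""
        L = np.zeros((self.K, self.K))
        for s, t in zip(self.src, self.tgt):
            L[t, s] += 1.0
            L[s, s] -= 1.0
        return L

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition ``(lam0, U)`` of L0, cached."""
        if self._eig is None:
            lam0, U = scipy.linalg.eigh(self.laplacian0())
            self._eig = (np.ascontiguousarray(lam0), np.ascontiguousarray(U))
        return self._eig


def compile_model(model: ReactionDiffusionModel) -> CompiledModel:
    K = model.n_compartments
    S = model.n_species
    kx, ky = model.grid.shape
    h = model.grid.spacing
    lam = model.lambda_array()
    jump_rate = np.array(
        [s.diffusion_coefficient / h**2 for s in model.species]
    )
    R = len(model.reactions)
    stoich = np.zeros((R, S), dtype=np.int64)
    net = np.zeros((R, S), dtype=np.float64)
    pref = np.zeros((K, R), dtype=np.float64)
    for r, rx in enumerate(model.reactions):
        lam_ref = model.reference_lambda(rx)
        denom = 1.0
        for sp, s in rx.reactants.items():
            i = model.species_index(sp)
            stoich[r, i] = s
            denom *= lam[i] ** s
        for i in model._changed_species(rx):
            sp = model.species[i].name
            d = rx.products.get(sp, 0) - rx.reactants.get(sp, 0)
            net[r, i] = d * round(lam[i] / lam_ref)
        prof = np.ones(K) if rx.profile is None else rx.profile
        pref[:, r] = lam_ref * rx.rate * prof / denom

    src, tgt = canonical_edges(model.grid)
    xcol = model.grid.x_index().astype(np.int64)

    nbr_lists: list[list[int]] = [[] for _ in range(K)]
    for s, t in zip(src, tgt):
        nbr_lists[s].append(int(t))
    maxdeg = max((len(v) for v in nbr_lists), default=1)
    maxdeg = max(maxdeg, 1)
    nbr = np.full((K, maxdeg), -1, dtype=np.int64)
    nbr_cnt = np.zeros(K, dtype=np.int64)
    for k, lst in enumerate(nbr_lists):
        nbr_cnt[k] = len(lst)
        for j, t in enumerate(lst):
            nbr[k, j] = t

    jumpw = jump_rate[None, :] * nbr_cnt[:, None].astype(float)
    dspec = np.where(jump_rate > 0)[0].astype(np.int64)

    return CompiledModel(
        K=K, S=S, Kx=kx, Ky=ky, h=h,
        lam=lam, jump_rate=jump_rate,
        stoich=stoich, net=net, pref=pref,
        src=src, tgt=tgt, xcol=xcol,
        nbr=nbr, nbr_cnt=nbr_cnt, jumpw=jumpw, dspec=dspec,
    )
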