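"""Exact spatial stochastic simulation (direct-method Gillespie SSA).

The spatial SSA treats every reaction channel in every compartment plus every
directed diffusive jump channel as one event stream: waiting times are
exponential in the total propensity, the firing channel is chosen with
probability proportional to its propensity, and the state is updated by the
channel's stoichiometric change.  This simulates the reaction-diffusion
master equation exactly and serves as the reference against which the hybrid
method is validated.

Two engines are provided: a numba-compiled direct method (default, used for
ensembles) and a plain-Python reference engine that can additionally record
every event.  Both draw channels in the same conceptual order but do not
share random streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _kernels
from .model import (
    InvariantViolationError,
    ReactionDiffusionModel,
    SystemState,
    reaction_propensity,
)

__all__ = [
    "EventRecord",
    "Trajectory",
    "ssa_simulate",
    "ssa_diffusion_only",
    "write_trajectory",
    "read_trajectory",
]


@dataclass(frozen=True)
class EventRecord:
    """One fired channel: ('reaction', (compartment, reaction_index)) or
    ('jump', (species_index, source, target))."""

    time: float
    kind: str
    channel: tuple


@dataclass
class Trajectory:
    """States sampled at fixed times along one stochastic realization.

    The snapshot convention is the state immediately after the last event at
    or before each sample time.
    """

    sample_times: np.ndarray
    states: np.ndarray  # (nT, K, S) int64
    rng_seed: int | None = None
    method: str = "ssa"
    clamp_loss: float = 0.0
    events: list[EventRecord] | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        st = np.asarray(self.states)
        if np.any(st < 0):
            raise InvariantViolationError("trajectory snapshots must be non-negative")
        self.states = st.astype(np.int64)

    def state_at(self, i: int) -> SystemState:
        return SystemState(self.states[i].copy(), float(self.sample_times[i]))

    def counts(self, species: str, model: ReactionDiffusionModel) -> np.ndarray:
        return self.states[:, :, model.species_index(species)]


def _resolve_seed(rng) -> int:
    """A 31-bit seed for the compiled kernels from int/SeedSequence/Generator."""
    if rng is None:
        rng = np.random.SeedSequence()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.SeedSequence(int(rng))
    if isinstance(rng, np.random.SeedSequence):
        return int(rng.generate_state(1, np.uint32)[0] % (2**31))
    if isinstance(rng, np.random.Generator):
        return int(rng.integers(2**31))
    raise TypeError(f"cannot derive a seed from {rng!r}")


def _check_sampling(initial: SystemState, t_end: float, sample_times) -> np.ndarray:
    ts = np.asarray(sample_times, dtype=float)
    if ts.ndim != 1 or ts.size == 0:
        raise ValueError("sample_times must be a non-empty 1-D sequence")
    if np.any(np.diff(ts) < 0):
        raise ValueError("sample_times must be non-decreasing")
    if t_end < initial.time:
        raise ValueError("t_end must be >= the initial time")
    if ts[0] < initial.time - 1e-12 or ts[-1] > t_end + 1e-12:
        raise ValueError("sample_times must lie within [initial.time, t_end]")
    return ts


def ssa_simulate(
    model: ReactionDiffusionModel,
    initial: SystemState,
    t_end: float,
    sample_times: Sequence[float],
    rng=None,
    engine: str = "compiled",
    record_events: bool = False,
) -> Trajectory:
    """Exact SSA realization of the model from ``initial`` to ``t_end``."""
    ts = _check_sampling(initial, t_end, sample_times)
    if initial.counts.shape != (model.n_compartments, model.n_species):
        raise InvariantViolationError("initial state shape does not match model")
    if record_events and engine == "compiled":
        engine = "reference"

    if engine == "compiled":
        cm = model.compiled()
        seed = _resolve_seed(rng)
        X = initial.counts.astype(np.float64)
        _kernels.seed_rng(seed)
        out, clamp_loss = _kernels.ssa_kernel(
            X, initial.time, ts, cm.stoich, cm.net, cm.pref,
            cm.jump_rate, cm.jumpw, cm.nbr, cm.nbr_cnt,
        )
        return Trajectory(ts, np.round(out), rng_seed=seed, method="ssa",
                          clamp_loss=float(clamp_loss))
    if engine == "reference":
        return _ssa_reference(model, initial, ts, rng, record_events)
    raise ValueError(f"unknown engine {engine!r}")


def _ssa_reference(model, initial, ts, rng, record_events) -> Trajectory:
    """Readable direct-method SSA; used for tiny systems and event logs."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cm = model.compiled()
    K, S = cm.K, cm.S
    X = initial.counts.astype(float)
    state = SystemState(initial.counts.copy(), initial.time)
    t = initial.time
    out = np.empty((ts.size, K, S))
    events: list[EventRecord] = [] if record_events else None
    si = 0
    clamp_loss = 0.0
    while si < ts.size:
        props = []
        for k in range(K):
            for r in range(len(model.reactions)):
                a = reaction_propensity(model.reactions[r], state, k, model)
                props.append((a, "reaction", (k, r)))
            for i in range(S):
                w = cm.jump_rate[i]
                if w > 0:
                    for j in range(cm.nbr_cnt[k]):
                        props.append(
                            (w * X[k, i], "jump", (i, k, int(cm.nbr[k, j])))
                        )
        a_vec = np.array([p[0] for p in props])
        a_tot = a_vec.sum()
        if a_tot <= 0:
            while si < ts.size:
                out[si] = X
                si += 1
            break
        t_next = t + rng.exponential(1.0 / a_tot)
        while si < ts.size and ts[si] < t_next:
            out[si] = X
            si += 1
        if si >= ts.size:
            break
        t = t_next
        idx = int(np.searchsorted(np.cumsum(a_vec), rng.random() * a_tot))
        idx = min(idx, len(props) - 1)
        _, kind, chan = props[idx]
        if kind == "reaction":
            k, r = chan
            X[k] += cm.net[r]
            neg = X[k] < 0
            clamp_loss += float(-X[k][neg].sum())
            X[k][neg] = 0.0
        else:
            i, k, nb = chan
            X[k, i] -= 1
            X[nb, i] += 1
        state = SystemState(X.astype(np.int64), t)
        X = state.counts.astype(float)
        if record_events:
            events.append(EventRecord(t, kind, chan))
    return Trajectory(ts, np.round(out), rng_seed=None, method="ssa",
                      clamp_loss=clamp_loss, events=events)


def write_trajectory(traj: Trajectory, path, model: ReactionDiffusionModel) -> None:
    """Write a trajectory as wide CSV (time, compartment, species, count)
    with a JSON metadata sidecar (model hash, seed, method, diagnostics)."""
    import json
    from pathlib import Path

    import pandas as pd

    base = Path(path)
    nT, K, S = traj.states.shape
    t_idx, k_idx, s_idx = np.meshgrid(
        np.arange(nT), np.arange(K), np.arange(S), indexing="ij"
    )
    names = np.array([sp.name for sp in model.species])
    pd.DataFrame({
        "time": traj.sample_times[t_idx.ravel()],
        "compartment": k_idx.ravel() + 1,  # 1-based on disk
        "species": names[s_idx.ravel()],
        "count": traj.states.ravel(),
    }).to_csv(base.with_suffix(".csv"), index=False)
    meta = {
        "model_hash": model.content_hash(),
        "species": list(names),
        "shape": [int(nT), int(K), int(S)],
        "sample_times": [float(t) for t in traj.sample_times],
        "rng_seed": traj.rng_seed,
        "method": traj.method,
        "clamp_loss": traj.clamp_loss,
        "diagnostics": {k: v for k, v in traj.diagnostics.items()
                        if np.isscalar(v)},
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_trajectory(path) -> Trajectory:
    """Round trip of :func:`write_trajectory`."""
    import json
    from pathlib import Path

    import pandas as pd

    base = Path(path)
    meta = json.loads(base.with_suffix(".json").read_text())
    df = pd.read_csv(base.with_suffix(".csv"))
    nT, K, S = meta["shape"]
    times = np.asarray(meta["sample_times"], dtype=float)
    t_index = {t: i for i, t in enumerate(times)}
    sp_index = {s: i for i, s in enumerate(meta["species"])}
    states = np.zeros((nT, K, S), dtype=np.int64)
    states[df["time"].map(t_index).to_numpy(),
           df["compartment"].to_numpy() - 1,
           df["species"].map(sp_index).to_numpy()] = df["count"].to_numpy()
    return Trajectory(times, states, rng_seed=meta.get("rng_seed"),
                      method=meta.get("method", "ssa"),
                      clamp_loss=meta.get("clamp_loss", 0.0),
                      diagnostics=meta.get("diagnostics", {}))


def ssa_diffusion_only(
    model: ReactionDiffusionModel,
    species: str,
    region: Iterable[int],
    t0: float,
    t1: float,
    state: SystemState,
    rng=None,
    record_jump_counts: bool = False,
):
    """Simulate only the diffusive jumps of ``species`` inside ``region``.

    ``region`` is a set of (0-based) compartment indices; jump channels
    crossing the region boundary are disabled, which realizes the reflective
    wall of the hybrid method's SSA sub-domain.  Counts outside the region
    are untouched and the regional total is conserved exactly.

    Returns the updated per-compartment counts of the species (length K), or
    ``(counts, jump_counts, (src, tgt))`` when ``record_jump_counts``.
    """
    cm = model.compiled()
    i = model.species_index(species)
    if cm.jump_rate[i] <= 0:
        from .model import ModelSpecificationError

        raise ModelSpecificationError(f"species {species!r} is not diffusive")
    if t1 < t0:
        raise ValueError("interval must have t1 >= t0")
    region = set(int(k) for k in region)
    for k in region:
        if not 0 <= k < cm.K:
            raise ValueError(f"region compartment {k} out of range")
    mask = np.array(
        [(s in region and t in region) for s, t in zip(cm.src, cm.tgt)]
    )
    esrc = cm.src[mask]
    etgt = cm.tgt[mask]
    x = state.counts[:, i].astype(np.float64)
    counts = np.zeros(esrc.size)
    _kernels.seed_rng(_resolve_seed(rng))
    _kernels.diffuse_ssa(x, t1 - t0, cm.jump_rate[i], esrc, etgt, counts,
                         record_jump_counts)
    x = np.round(x).astype(np.int64)
    if record_jump_counts:
        return x, counts, (esrc, etgt)
    return x
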