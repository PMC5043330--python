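"""Ensemble orchestration, method comparison and the Poisson-Gaussian
diagnostic.

Replicate r of an ensemble uses an independent random stream derived from
``(master_seed, r)`` via NumPy's SeedSequence, so summaries are bit-for-bit
reproducible and permutation-invariant in replicate order.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.special

from .hybrid import HybridConfig, hybrid_simulate
from .model import ReactionDiffusionModel, SystemState
from .ssa import ssa_simulate

__all__ = [
    "EnsembleSummary",
    "ComparisonReport",
    "run_ensemble",
    "relative_difference",
    "poisson_gaussian_max_diff",
    "write_summary",
    "read_summary",
]


@dataclass
class EnsembleSummary:
    """Per-(compartment, species, time) ensemble means and SDs."""

    sample_times: np.ndarray        # (nT,)
    species: list[str]
    mean: np.ndarray                # (nT, K, S)
    sd: np.ndarray                  # (nT, K, S), (n-1)-denominator
    runs: int
    master_seed: int
    method: str
    model_hash: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.runs >= 2 and np.any(self.sd < 0):
            raise ValueError("standard deviations must be >= 0")

    def species_slice(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.species.index(name)
        return self.mean[:, :, i], self.sd[:, :, i]


@dataclass
class ComparisonReport:
    """Relative differences (reference - other) / reference, masked to
    compartments where the reference mean reaches the inclusion floor."""

    rel_mean: np.ndarray            # (nT, K, S), NaN outside the mask
    rel_sd: np.ndarray
    mask: np.ndarray                # bool, inclusion mask
    floor: float
    max_abs_mean: float
    max_abs_sd: float

    @property
    def max_abs(self) -> float:
        return max(self.max_abs_mean, self.max_abs_sd)


def _replicate_seed(master_seed: int, r: int) -> np.random.SeedSequence:
    return np.random.SeedSequence((int(master_seed), int(r)))


def run_ensemble(
    model: ReactionDiffusionModel,
    method: str,
    runs: int,
    t_end: float,
    sample_times: Sequence[float],
    config: HybridConfig | None = None,
    master_seed: int = 0,
    initial: SystemState | None = None,
    progress: bool = False,
) -> EnsembleSummary:
    """Run ``runs`` replicates of the chosen method and summarize them."""
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if initial is None:
        raise ValueError("an initial SystemState is required")
    if method not in ("ssa", "hybrid"):
        raise ValueError("method must be 'ssa' or 'hybrid'")
    ts = np.asarray(sample_times, dtype=float)
    acc = None
    acc2 = None
    t_wall = _time.perf_counter()
    for r in range(runs):
        seed = _replicate_seed(master_seed, r)
        if method == "ssa":
            traj = ssa_simulate(model, initial, t_end, ts, rng=seed)
        else:
            traj = hybrid_simulate(model, initial, t_end, ts,
                                   config=config, rng=seed)
        x = traj.states.astype(np.float64)
        if acc is None:
            acc = np.zeros_like(x)
            acc2 = np.zeros_like(x)
        acc += x
        acc2 += x * x
        if progress and (r + 1) % 20 == 0:  # pragma: no cover
            print(f"  {method}: {r + 1}/{runs} replicates", flush=True)
    mean = acc / runs
    if runs >= 2:
        var = np.clip((acc2 - runs * mean**2) / (runs - 1), 0.0, None)
        sd = np.sqrt(var)
    else:
        sd = np.zeros_like(mean)
    meta = {
        "t_end": float(t_end),
        "wall_time_s": _time.perf_counter() - t_wall,
    }
    if config is not None:
        meta["ta"] = config.ta
        meta["adaptivity_mode"] = (
            config.adaptivity_mode
            if isinstance(config.adaptivity_mode, str)
            else dict(config.adaptivity_mode)
        )
    return EnsembleSummary(
        sample_times=ts,
        species=[s.name for s in model.species],
        mean=mean,
        sd=sd,
        runs=runs,
        master_seed=int(master_seed),
        method=method,
        model_hash=model.content_hash(),
        metadata=meta,
    )


def relative_difference(
    reference: EnsembleSummary,
    other: EnsembleSummary,
    floor: float = 5.0,
) -> ComparisonReport:
    """(reference - other) / reference for means and SDs, restricted to
    entries whose reference mean is at least ``floor`` molecules."""
    if reference.mean.shape != other.mean.shape:
        raise ValueError("summaries have different shapes")
    if not np.allclose(reference.sample_times, other.sample_times):
        raise ValueError("summaries have different sample times")
    mask = reference.mean >= floor
    rel_mean = np.full_like(reference.mean, np.nan)
    rel_sd = np.full_like(reference.mean, np.nan)
    rel_mean[mask] = (reference.mean[mask] - other.mean[mask]) / reference.mean[mask]
    sd_ok = mask & (reference.sd > 0)
    rel_sd[sd_ok] = (reference.sd[sd_ok] - other.sd[sd_ok]) / reference.sd[sd_ok]
    max_mean = float(np.nanmax(np.abs(rel_mean))) if mask.any() else np.nan
    max_sd = float(np.nanmax(np.abs(rel_sd))) if sd_ok.any() else np.nan
    return ComparisonReport(rel_mean, rel_sd, mask, float(floor), max_mean, max_sd)


def poisson_gaussian_max_diff(mu: float) -> float:
    """max_n |Normal(mu, mu) density - Poisson(mu) pmf| over integers n >= 0.

    This quantifies where a Gaussian stops being an acceptable surrogate for
    Poissonian jump counts; at mu = 10 the value drops below 0.01, the basis
    of the default cut-off T_A = 10.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    n_hi = int(np.ceil(mu + 12.0 * np.sqrt(mu) + 20.0))
    n = np.arange(0, n_hi + 1, dtype=float)
    log_pois = n * np.log(mu) - mu - scipy.special.gammaln(n + 1.0)
    pois = np.exp(log_pois)
    gauss = np.exp(-((n - mu) ** 2) / (2.0 * mu)) / np.sqrt(2.0 * np.pi * mu)
    return float(np.max(np.abs(gauss - pois)))


# ---------------------------------------------------------------------------
# summary file round trip
# ---------------------------------------------------------------------------


def write_summary(summary: EnsembleSummary, path) -> None:
    """Write ``<path>.csv`` (compartment, species, time, mean, sd) and a
    ``<path>.json`` metadata sidecar."""
    base = Path(path)
    nT, K, S = summary.mean.shape
    t_idx, k_idx, s_idx = np.meshgrid(
        np.arange(nT), np.arange(K), np.arange(S), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "compartment": k_idx.ravel() + 1,  # 1-based on disk
            "species": np.array(summary.species)[s_idx.ravel()],
            "time": summary.sample_times[t_idx.ravel()],
            "mean": summary.mean.ravel(),
            "sd": summary.sd.ravel(),
        }
    )
    df.to_csv(base.with_suffix(".csv"), index=False)
    meta = {
        "species": summary.species,
        "sample_times": [float(t) for t in summary.sample_times],
        "shape": [nT, K, S],
        "runs": summary.runs,
        "master_seed": summary.master_seed,
        "method": summary.method,
        "model_hash": summary.model_hash,
        "metadata": summary.metadata,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_summary(path) -> EnsembleSummary:
    base = Path(path)
    meta = json.loads(base.with_suffix(".json").read_text())
    df = pd.read_csv(base.with_suffix(".csv"))
    nT, K, S = meta["shape"]
    expected = {"compartment", "species", "time", "mean", "sd"}
    if set(df.columns) != expected:
        raise ValueError(f"summary schema mismatch: {sorted(df.columns)}")
    mean = np.empty((nT, K, S))
    sd = np.empty((nT, K, S))
    sp_index = {s: i for i, s in enumerate(meta["species"])}
    times = np.asarray(meta["sample_times"], dtype=float)
    t_index = {t: i for i, t in enumerate(times)}
    ti = df["time"].map(t_index).to_numpy()
    ki = df["compartment"].to_numpy() - 1
    si = df["species"].map(sp_index).to_numpy()
    mean[ti, ki, si] = df["mean"].to_numpy()
    sd[ti, ki, si] = df["sd"].to_numpy()
    return EnsembleSummary(
        sample_times=times,
        species=list(meta["species"]),
        mean=mean,
        sd=sd,
        runs=int(meta["runs"]),
        master_seed=int(meta["master_seed"]),
        method=meta["method"],
        model_hash=meta.get("model_hash", ""),
        metadata=meta.get("metadata", {}),
    )
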