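"""Simulation-based calibration of the detector's two thresholds.

Even purely free motion produces small diagonal blocks, because escaping a
region of size ``lam`` takes a random finite time. Two quantities are
therefore calibrated against a chosen reference model of free motion
(Brownian, or subdiffusive fBm with H = 0.35), per dimension and test
lengthscale:

* ``n_d`` — the number of diagonal lines added on each side of the matrix
  diagonal, set to the 10th percentile of block times pooled over
  reference trajectories (pipeline run through hole filling, no banding);
* ``tau_pval`` — the minimal block size incompatible with free motion at a
  given p-value: the smallest size s whose empirical CDF under the null
  (full pipeline, candidate blocks at nu > nu_c) reaches 1 - pval.

Calibrations are persisted as a JSON table keyed by
(model, dim, lambda, mu).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.random import Generator, default_rng

from .measures import block_times, candidate_blocks, diagonal_measures
from .recurrence import binary_pipeline
from .simulate import simulate_bm, simulate_fbm
from .trajectory_io import Trajectory, standardize

__all__ = [
    "CalibrationError",
    "CalibrationEntry",
    "CalibrationTable",
    "calibrate_band_count",
    "calibrate_null_blocks",
    "min_block_size",
    "calibrate_entry",
]


class CalibrationError(ValueError):
    """Calibration inputs are empty or inconsistent."""


@dataclass(frozen=True)
class CalibrationEntry:
    """Calibrated thresholds for one (model, dim, lambda, mu) combination."""

    model: str
    dim: int
    lam: float
    mu: int
    n_d: int
    ecdf_sizes: tuple[int, ...]
    ecdf_probs: tuple[float, ...]
    tau_pval: dict[float, int]

    def min_block(self, p_value: float) -> int:
        key = round(float(p_value), 10)
        for p, tau in self.tau_pval.items():
            if round(float(p), 10) == key:
                return tau
        return min_block_size(np.array(self.ecdf_sizes), np.array(self.ecdf_probs), p_value)


@dataclass
class CalibrationTable:
    """Collection of calibration entries plus provenance metadata."""

    entries: dict[tuple[str, int, float, int], CalibrationEntry] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def add(self, entry: CalibrationEntry) -> None:
        self.entries[(entry.model, entry.dim, entry.lam, entry.mu)] = entry

    def get(self, model: str, dim: int, lam: float, mu: int) -> CalibrationEntry:
        try:
            return self.entries[(model, dim, float(lam), mu)]
        except KeyError:
            raise CalibrationError(
                f"no calibration for model={model}, dim={dim}, lambda={lam}, mu={mu}"
            ) from None

    def save(self, path) -> None:
        payload = {
            "metadata": self.metadata,
            "entries": [
                {**asdict(e), "tau_pval": {str(p): t for p, t in e.tau_pval.items()}}
                for e in self.entries.values()
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "CalibrationTable":
        with open(path) as fh:
            payload = json.load(fh)
        table = cls(metadata=payload.get("metadata", {}))
        for raw in payload["entries"]:
            raw["tau_pval"] = {float(p): int(t) for p, t in raw["tau_pval"].items()}
            raw["ecdf_sizes"] = tuple(int(s) for s in raw["ecdf_sizes"])
            raw["ecdf_probs"] = tuple(float(p) for p in raw["ecdf_probs"])
            table.add(CalibrationEntry(**raw))
        return table


def _reference_trajectory(
    model: str, dim: int, n_steps: int, rng: Generator, hurst: float = 0.35
) -> Trajectory:
    if model == "bm":
        return simulate_bm(n_steps, dim, sigma=1.0, seed=rng)
    if model == "fbm":
        return simulate_fbm(n_steps, dim, hurst=hurst, sigma=1.0, seed=rng)
    raise ValueError(f"unknown reference model {model!r}")


def calibrate_band_count(
    model: str,
    dim: int,
    lam: float,
    mu: int = 2,
    n_traj: int = 1000,
    n_steps: int = 2000,
    seed=None,
    hurst: float = 0.35,
) -> int:
    """Band count ``n_d`` as the 10th percentile of null block times.

    Simulates ``n_traj`` standardized reference trajectories, runs the
    matrix pipeline through hole filling (no banding), and pools the
    vertical block time over the frames of all trajectories. Frames whose
    diagonal entry did not survive thresholding carry no block time (the
    run-length definition presumes a unit diagonal entry) and are
    excluded from the pool. The nearest-rank 10th percentile of the
    pooled distribution is returned. A small percentile keeps the band
    short enough to separate nearby traps while still bridging the
    sparse diagonal of free motion.
    """
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    pooled = []
    for _ in range(n_traj):
        traj = standardize(_reference_trajectory(model, dim, n_steps, rng, hurst))
        B = binary_pipeline(traj, lam, mu, n_d=None)
        tb = block_times(B)
        pooled.append(tb[tb > 0])
    values = np.sort(np.concatenate(pooled))
    if values.size == 0:
        raise CalibrationError("no surviving diagonal entries in band-count calibration")
    # nearest-rank percentile: smallest value with ECDF >= 0.10
    k = max(math.ceil(0.10 * len(values)), 1) - 1
    return int(values[k])


def calibrate_null_blocks(
    model: str,
    dim: int,
    lam: float,
    mu: int,
    n_d: int,
    n_traj: int = 1000,
    n_steps: int = 10000,
    nu_c: float = 0.75,
    seed=None,
    hurst: float = 0.35,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of candidate block sizes under the free-motion null.

    Runs the full pipeline (including banding with the calibrated ``n_d``)
    on each reference trajectory and collects the sizes of all runs with
    ``nu > nu_c``. Returns ``(sizes, probs)``: unique sizes in increasing
    order and the empirical CDF evaluated at them.
    """
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    sizes: list[int] = []
    for _ in range(n_traj):
        traj = standardize(_reference_trajectory(model, dim, n_steps, rng, hurst))
        B = binary_pipeline(traj, lam, mu, n_d=n_d)
        blocks = candidate_blocks(diagonal_measures(B), nu_c)
        sizes.extend(b.size for b in blocks)
    if not sizes:
        raise CalibrationError("no candidate blocks observed under the null")
    arr = np.sort(np.asarray(sizes, dtype=np.int64))
    uniq, counts = np.unique(arr, return_counts=True)
    probs = np.cumsum(counts) / len(arr)
    return uniq, probs


def min_block_size(ecdf_sizes: np.ndarray, ecdf_probs: np.ndarray, p_value: float) -> int:
    """Smallest block size s with ``ECDF(s) >= 1 - p_value``.

    Blocks at least this long are rejected as chance occurrences under the
    reference free motion with probability <= p_value.
    """
    if not 0.0 < p_value < 1.0:
        raise ValueError("p_value must be in (0, 1)")
    sizes = np.asarray(ecdf_sizes)
    probs = np.asarray(ecdf_probs)
    if sizes.size == 0:
        raise CalibrationError("empty ECDF")
    hit = np.flatnonzero(probs >= 1.0 - p_value)
    if hit.size == 0:
        # even the largest observed null block is too common; be conservative
        return int(sizes[-1]) + 1
    return int(sizes[hit[0]])


def calibrate_entry(
    model: str,
    dim: int,
    lam: float,
    mu: int = 2,
    p_values: tuple[float, ...] = (0.05,),
    n_traj_band: int = 1000,
    n_steps_band: int = 2000,
    n_traj_null: int = 1000,
    n_steps_null: int = 10000,
    nu_c: float = 0.75,
    seed=None,
    hurst: float = 0.35,
) -> CalibrationEntry:
    """Full calibration for one (model, dim, lambda, mu) combination.

    The two stages consume independent random streams derived from
    ``seed``. Defaults use the full reference scale (10^3 trajectories,
    2x10^3 steps for the band count, 10^4 for the null); reduced scales
    are first-class for desk-scale runs.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    band_seed, null_seed = ss.spawn(2)
    n_d = calibrate_band_count(
        model, dim, lam, mu, n_traj_band, n_steps_band, default_rng(band_seed), hurst
    )
    sizes, probs = calibrate_null_blocks(
        model, dim, lam, mu, n_d, n_traj_null, n_steps_null, nu_c, default_rng(null_seed), hurst
    )
    tau = {float(p): min_block_size(sizes, probs, p) for p in p_values}
    return CalibrationEntry(
        model, dim, float(lam), mu, n_d,
        tuple(int(s) for s in sizes), tuple(float(p) for p in probs), tau,
    )
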