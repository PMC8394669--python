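"""Trajectory containers, CSV input/output, and scale standardization.

Trajectories are tables of ``(traj_id, frame, x, y[, z])``. All downstream
analysis operates on standardized trajectories, whose one-step increments
have unit empirical standard deviation on every coordinate; this makes the
detection results independent of the diffusion coefficient and of the
length units of the raw data.
"""

from __future__ import annotations

import json
import logging

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "Block",
    "SegmentationResult",
    "TrajectoryFormatError",
    "TrajectoryDataError",
    "DegenerateTrajectoryError",
    "read_trajectories",
    "write_trajectories",
    "write_segmentation",
    "standardize",
]

DEFAULT_DIALECT = {"id": "traj_id", "frame": "frame", "x": "x", "y": "y", "z": "z"}


class TrajectoryFormatError(ValueError):
    """Input table cannot be mapped to the required columns."""


class TrajectoryDataError(ValueError):
    """Input rows violate trajectory invariants (e.g. duplicate frames)."""


class DegenerateTrajectoryError(ValueError):
    """Trajectory has zero increment variance on some coordinate."""


@dataclass(frozen=True)
class Trajectory:
    """Ordered positions of one particle in 2 or 3 dimensions.

    Parameters
    ----------
    id : str
        Trajectory identifier.
    frames : ndarray of int, shape (N,)
        Strictly increasing frame indices.
    positions : ndarray of float, shape (N, dim)
        Particle coordinates; dim must be 2 or 3. Units are arbitrary
        (experimental data typically in micrometres).
    frame_interval : float, optional
        Acquisition interval in seconds (default 1).
    """

    id: str
    frames: np.ndarray
    positions: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        positions = np.asarray(self.positions, dtype=np.float64)
        if positions.ndim != 2 or positions.shape[1] not in (2, 3):
            raise TrajectoryFormatError(
                f"positions must be (N, 2) or (N, 3); got shape {positions.shape}"
            )
        if len(frames) != len(positions):
            raise TrajectoryFormatError("frames and positions length mismatch")
        if len(frames) < 2:
            raise TrajectoryDataError("a trajectory needs at least 2 points")
        if np.any(np.diff(frames) <= 0):
            raise TrajectoryDataError(
                f"frames of trajectory {self.id!r} are not strictly increasing"
            )
        if not np.all(np.isfinite(positions)):
            raise TrajectoryDataError(f"trajectory {self.id!r} has non-finite coordinates")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "positions", positions)

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def dim(self) -> int:
        return self.positions.shape[1]


@dataclass(frozen=True)
class Block:
    """A contiguous run of trapped frames, 1-based inclusive endpoints."""

    start: int
    end: int
    lam: float | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid block [{self.start}, {self.end}]")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SegmentationResult:
    """Per-frame trapped/free labelling of one trajectory.

    ``labels`` is a boolean array (True = trapped) consistent with
    ``blocks``: a frame is True exactly when it lies inside a block.
    """

    trajectory_id: str
    labels: np.ndarray
    blocks: tuple[Block, ...]
    lambdas_used: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=bool)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "blocks", tuple(self.blocks))
        object.__setattr__(self, "lambdas_used", tuple(self.lambdas_used))
        n = len(labels)
        covered = np.zeros(n, dtype=bool)
        last_end = 0
        for b in self.blocks:
            if b.start <= last_end:
                raise ValueError("blocks must be sorted and disjoint")
            if b.end > n:
                raise ValueError(f"block [{b.start}, {b.end}] outside trajectory of length {n}")
            covered[b.start - 1 : b.end] = True
            last_end = b.end
        if not np.array_equal(covered, labels):
            raise ValueError("labels and blocks are inconsistent")

    @property
    def n_trapped(self) -> int:
        return int(self.labels.sum())


def blocks_from_labels(labels: np.ndarray, lam: float | None = None) -> tuple[Block, ...]:
    """Maximal runs of True in ``labels`` as 1-based Blocks."""
    labels = np.asarray(labels, dtype=bool)
    if not labels.any():
        return ()
    padded = np.concatenate([[False], labels, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    return tuple(Block(int(s), int(e), lam) for s, e in zip(starts, ends))


def read_trajectories(
    path, dialect: dict[str, str] | None = None, frame_interval: float = 1.0
) -> list[Trajectory]:
    """Read trajectories from a CSV with columns (id, frame, x, y[, z]).

    Parameters
    ----------
    path : str or path-like
        CSV file with a header row.
    dialect : dict, optional
        Mapping from the roles ``id, frame, x, y, z`` to actual column
        names; defaults to ``traj_id, frame, x, y, z``.

    Returns
    -------
    list of Trajectory, one per distinct id, rows sorted by frame.
    The dimensionality is 3 when a z column is present, else 2.
    """
    names = dict(DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)
    df = pd.read_csv(path, float_precision="round_trip")
    for role in ("id", "frame", "x", "y"):
        if names[role] not in df.columns:
            raise TrajectoryFormatError(
                f"required column {names[role]!r} (role {role!r}) missing from {path}"
            )
    coord_cols = [names["x"], names["y"]]
    if names["z"] in df.columns:
        coord_cols.append(names["z"])

    out: list[Trajectory] = []
    for tid, sub in df.groupby(names["id"], sort=False):
        sub = sub.sort_values(names["frame"], kind="mergesort")
        frames = sub[names["frame"]].to_numpy(dtype=np.int64)
        if np.any(np.diff(frames) == 0):
            raise TrajectoryDataError(f"duplicate frames in trajectory {tid!r}")
        if len(frames) > 1 and np.any(np.diff(frames) != np.diff(frames)[0]):
            logger.warning("trajectory %r has non-uniform frame spacing; steps are "
                           "treated as contiguous", tid)
        positions = sub[coord_cols].to_numpy(dtype=np.float64)
        if np.isnan(positions).any():
            raise TrajectoryDataError(f"missing coordinates in trajectory {tid!r}")
        out.append(Trajectory(str(tid), frames, positions, frame_interval))
    return out


def write_trajectories(trajectories: list[Trajectory], path) -> None:
    """Write trajectories to CSV (columns traj_id, frame, x, y[, z])."""
    dims = {t.dim for t in trajectories}
    dim = max(dims) if dims else 2
    frames_parts = []
    for t in trajectories:
        d = {"traj_id": t.id, "frame": t.frames, "x": t.positions[:, 0], "y": t.positions[:, 1]}
        if dim == 3:
            d["z"] = t.positions[:, 2] if t.dim == 3 else np.zeros(t.n_points)
        frames_parts.append(pd.DataFrame(d))
    pd.concat(frames_parts, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def write_segmentation(results: list[SegmentationResult], csv_path, json_path=None) -> None:
    """Write per-frame labels to CSV and the block list to a JSON sidecar."""
    rows = []
    for res in results:
        block_id = np.full(len(res.labels), -1, dtype=int)
        for k, b in enumerate(res.blocks):
            block_id[b.start - 1 : b.end] = k
        rows.append(pd.DataFrame({
            "traj_id": res.trajectory_id,
            "frame": np.arange(1, len(res.labels) + 1),
            "label": np.where(res.labels, "trapped", "free"),
            "block_id": block_id,
        }))
    pd.concat(rows, ignore_index=True).to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            res.trajectory_id: {
                "lambdas_used": list(res.lambdas_used),
                "blocks": [
                    {"start": b.start, "end": b.end, "size": b.size, "lambda": b.lam}
                    for b in res.blocks
                ],
            }
            for res in results
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)


def standardize(traj: Trajectory) -> Trajectory:
    """Rescale each coordinate's one-step increments to unit standard deviation.

    The returned trajectory starts at the original first position and its
    positions are the cumulative sum of the rescaled increments, so results
    for Brownian motion no longer depend on the diffusion coefficient. The
    standard deviation is the sample estimate (mean subtracted, ddof=1) over
    the N-1 increments of each coordinate.

    Raises
    ------
    DegenerateTrajectoryError
        If any coordinate has zero increment variance (stuck particle).
    """
    if traj.n_points < 3:
        raise TrajectoryDataError("standardize needs at least 3 points")
    incr = np.diff(traj.positions, axis=0)
    sd = incr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateTrajectoryError(
            f"trajectory {traj.id!r} has zero increment variance on a coordinate"
        )
    scaled = incr / sd
    positions = np.empty_like(traj.positions)
    positions[0] = traj.positions[0]
    positions[1:] = traj.positions[0] + np.cumsum(scaled, axis=0)
    return replace(traj, positions=positions)
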