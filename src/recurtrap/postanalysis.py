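"""Summary statistics of segmented trajectories.

Covers the post-detection questions asked of experimental data: how big
are the traps (robust radius from the trapped portion geometry), how long
do trapping events last, what fraction of molecules is trapped per frame,
and how do the free portions diffuse (time-averaged MSD and its
anomalous-diffusion fit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .trajectory_io import Block, SegmentationResult, Trajectory

__all__ = [
    "TrapSummary",
    "TamsdFit",
    "trap_geometry",
    "tamsd",
    "fit_tamsd",
    "fraction_trapped",
    "MIN_FREE_PORTION",
]

#: minimal free-portion length (frames) retained for TAMSD fitting
MIN_FREE_PORTION = 50


@dataclass(frozen=True)
class TrapSummary:
    """Geometry of one trapped portion."""

    block: Block
    centre: np.ndarray
    radius: float

    @property
    def duration(self) -> int:
        return self.block.size


@dataclass(frozen=True)
class TamsdFit:
    """Anomalous-diffusion fit of a TAMSD curve.

    ``d_alpha`` is the generalized diffusion coefficient
    (length^2 / time^alpha), ``alpha`` the anomalous exponent and
    ``sigma_err`` the localisation error inferred from the constant
    offset ``2 dim sigma_err^2``.
    """

    d_alpha: float
    alpha: float
    sigma_err: float
    lag_range: tuple[int, int]
    converged: bool
    residual: float


def trap_geometry(traj: Trajectory, block: Block) -> TrapSummary:
    """Robust centre and radius of the trapped portion in ``block``.

    Centre is the coordinate-wise median; radius the nearest-rank 95th
    percentile of distances to the centre (the point further away than
    95% of points), which ignores occasional excursions.
    """
    if block.size < 2:
        raise ValueError("trap geometry needs a block of at least 2 frames")
    if block.end > traj.n_points:
        raise ValueError("block outside trajectory")
    pts = traj.positions[block.start - 1 : block.end]
    centre = np.median(pts, axis=0)
    dist = np.sort(np.linalg.norm(pts - centre, axis=1))
    k = max(math.ceil(0.95 * len(dist)), 1) - 1
    return TrapSummary(block, centre, float(dist[k]))


def tamsd(positions: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-averaged mean squared displacement, summed over coordinates.

    ``delta2[n-1] = mean_k |x_{k+n} - x_k|^2`` for lags n = 1..max_lag.
    """
    positions = np.asarray(positions, dtype=float)
    n_pts = positions.shape[0]
    if max_lag >= n_pts:
        raise ValueError("max_lag must be smaller than the portion length")
    out = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        d = positions[lag:] - positions[:-lag]
        out[lag - 1] = np.mean(np.sum(d * d, axis=1))
    return out


def fit_tamsd(
    delta2: np.ndarray,
    lag_range: tuple[int, int] = (1, 5),
    frame_interval: float = 1.0,
    dim: int = 2,
) -> TamsdFit:
    """Fit ``2 dim (D_alpha t^alpha + sigma_err^2)`` to a TAMSD curve.

    Lags in ``lag_range`` (inclusive, in frames) are converted to seconds
    via ``frame_interval``. Nonlinear least squares with positivity
    bounds, multi-started over alpha in {0.5, 1.0, 1.5} because a
    3-parameter power law on a handful of points is ill-conditioned.
    Non-convergence is reported in the ``converged`` flag rather than
    raised.
    """
    lo, hi = lag_range
    if hi - lo + 1 < 3:
        raise ValueError("lag_range must contain at least 3 lags")
    delta2 = np.asarray(delta2, dtype=float)
    if hi > len(delta2):
        raise ValueError("lag_range exceeds available lags")
    y = delta2[lo - 1 : hi]
    t = np.arange(lo, hi + 1) * frame_interval
    pref = 2.0 * dim

    def model(t, d_alpha, alpha, sigma_err):
        return pref * (d_alpha * t ** alpha + sigma_err ** 2)

    best = None
    scale = max(y[0] / pref, 1e-12)
    for alpha0 in (0.5, 1.0, 1.5):
        try:
            popt, _ = curve_fit(
                model, t, y, p0=[scale, alpha0, 0.0],
                bounds=([1e-15, 1e-6, 0.0], [np.inf, 4.0, np.inf]),
                maxfev=10000,
            )
        except RuntimeError:
            continue
        resid = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        return TamsdFit(np.nan, np.nan, np.nan, (lo, hi), False, np.inf)
    (d_alpha, alpha, sigma_err), resid = best
    return TamsdFit(float(d_alpha), float(alpha), float(sigma_err), (lo, hi), True, resid)


def fraction_trapped(
    results: list[SegmentationResult], grouping: dict[str, str] | None = None
) -> dict[str, float]:
    """Pooled fraction of trapped frames per group (e.g. per cell).

    ``grouping`` maps trajectory id to a group key; ungrouped analyses
    use a single implicit group "all". Groups with no frames are omitted.
    """
    totals: dict[str, list[int]] = {}
    for res in results:
        key = grouping.get(res.trajectory_id, None) if grouping else "all"
        if key is None:
            continue
        t = totals.setdefault(key, [0, 0])
        t[0] += int(res.labels.sum())
        t[1] += len(res.labels)
    return {k: t[0] / t[1] for k, t in totals.items() if t[1] > 0}
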