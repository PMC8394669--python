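"""Diagonal run-length measures, the block invariant, and block extraction.

For each diagonal position ``n`` of the binary recurrence matrix B, three
run lengths are measured (all runs of ones, truncated at the matrix
borders, no wrap-around):

* block time ``t_block`` — the vertical run through ``B[n, n]`` (the
  apparent trapping duration seen from frame n);
* neighbouring time ``t_perp`` — the anti-diagonal run through ``B[n, n]``
  (the window of frames colocalizing with frame n, counted on both sides);
* persistence time ``t_par`` — the run parallel to the main diagonal
  through the lower-left extremity of that anti-diagonal run, counted in
  both directions (how long the colocalization pattern persists).

Their combination

    nu(n) = t_block(n) / (t_par(n) + t_perp(n) - 1)

equals 1 at every diagonal position of an ideal all-ones block and drops
towards (2 n_d + 1) / N on free, banded stretches. A frame belongs to a
candidate trapping block when ``nu(n)`` exceeds the critical value ``nu_c``
(3/4 by default, tolerating moderately deformed blocks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recurrence import BinaryRecurrenceMatrix
from .trajectory_io import Block, blocks_from_labels

__all__ = [
    "DiagonalMeasures",
    "DetectionParams",
    "diagonal_measures",
    "block_times",
    "candidate_blocks",
    "filter_blocks",
]


@dataclass(frozen=True)
class DiagonalMeasures:
    """Per-frame run-length measures along the matrix diagonal."""

    t_block: np.ndarray  # t|, frames
    t_perp: np.ndarray   # t-perp, frames
    t_par: np.ndarray    # t-parallel, frames
    nu: np.ndarray       # block invariant, dimensionless


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of single-lengthscale detection.

    ``n_d`` (diagonal band half-width) and ``min_block`` (minimal
    significant block size at the chosen p-value) come from the
    simulation-based calibration for a given reference model, dimension
    and lengthscale.
    """

    lam: float
    n_d: int
    min_block: int
    mu: int = 2
    nu_c: float = 0.75
    p_value: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.nu_c <= 1.0:
            raise ValueError("nu_c must be in (0, 1]")
        if not 0.0 < self.p_value < 1.0:
            raise ValueError("p_value must be in (0, 1)")


class _LineRuns:
    """Run-length index of the 1-cells of a binary matrix along one line
    direction.

    Cells are grouped by a line id (column, anti-diagonal or diagonal
    index) and ordered by a position along the line; maximal runs of
    consecutive positions are extracted once, after which the run through
    any given cell is an O(log m) lookup. Exploits the sparsity of the
    binary recurrence matrix, whose 1-cells are confined to the band and
    the trapping blocks.
    """

    def __init__(self, line: np.ndarray, pos: np.ndarray, n: int) -> None:
        order = np.lexsort((pos, line))
        li = line[order]
        pi = pos[order]
        new = np.empty(len(li), dtype=bool)
        if len(li):
            new[0] = True
            new[1:] = (li[1:] != li[:-1]) | (pi[1:] != pi[:-1] + 1)
        run_id = np.cumsum(new) - 1
        starts = np.flatnonzero(new)
        self._keys = li * n + pi  # sorted ascending
        self._run_id = run_id
        self._run_start = pi[starts]
        self._run_len = np.diff(np.append(starts, len(li)))
        self._n = n

    def lookup(self, line: np.ndarray, pos: np.ndarray):
        """(run length, run start pos, found) for each queried cell."""
        q = line * self._n + pos
        if len(self._keys) == 0:
            z = np.zeros(len(q), dtype=np.int64)
            return z, z, np.zeros(len(q), dtype=bool)
        at = np.minimum(np.searchsorted(self._keys, q), len(self._keys) - 1)
        hit = self._keys[at] == q
        rid = self._run_id[at]
        return self._run_len[rid], self._run_start[rid], hit


def _cells(B: BinaryRecurrenceMatrix) -> tuple[np.ndarray, np.ndarray]:
    ii, jj = np.nonzero(B.values)
    return ii.astype(np.int64), jj.astype(np.int64)


def block_times(B: BinaryRecurrenceMatrix) -> np.ndarray:
    """Vertical run of ones through each diagonal entry (0 where the
    diagonal entry itself is 0). Used for band-count calibration, which
    runs before any banding guarantees a unit diagonal."""
    ii, jj = _cells(B)
    n = B.n
    vert = _LineRuns(jj, ii, n)
    idx = np.arange(n, dtype=np.int64)
    length, _, hit = vert.lookup(idx, idx)
    return np.where(hit, length, 0).astype(np.int64)


def diagonal_measures(B: BinaryRecurrenceMatrix) -> DiagonalMeasures:
    """Compute (t_block, t_perp, t_par, nu) at every diagonal position.

    Requires a unit diagonal (guaranteed after band augmentation). The
    parallel run is evaluated at the lower-left extremity of the
    anti-diagonal run; by symmetry of B the upper-right extremity gives
    the same value.
    """
    n = B.n
    idx = np.arange(n, dtype=np.int64)
    if not B.values[idx, idx].all():
        raise ValueError("diagonal of B must be all ones (apply add_diagonal_bands)")
    ii, jj = _cells(B)

    vert = _LineRuns(jj, ii, n)
    t_block, _, _ = vert.lookup(idx, idx)
    t_block = t_block.astype(np.int64)

    # anti-diagonals: line id i + j, position i (down-left = increasing i)
    anti = _LineRuns(ii + jj, ii, n)
    t_perp, a_start, _ = anti.lookup(2 * idx, idx)
    t_perp = t_perp.astype(np.int64)
    er = a_start + t_perp - 1          # lower-left extremity (row)
    ec = 2 * idx - er                  # and column

    # main diagonals: line id j - i (shifted non-negative), position i
    diag = _LineRuns(jj - ii + n, ii, n)
    t_par, _, _ = diag.lookup(ec - er + n, er)
    t_par = t_par.astype(np.int64)

    nu = t_block / (t_par + t_perp - 1.0)
    return DiagonalMeasures(t_block, t_perp, t_par, nu)


def candidate_blocks(
    measures: DiagonalMeasures, nu_c: float = 0.75, lam: float | None = None
) -> list[Block]:
    """Maximal runs of frames with ``nu > nu_c`` (strict), as 1-based blocks."""
    return list(blocks_from_labels(measures.nu > nu_c, lam))


def filter_blocks(blocks: list[Block], min_block: int) -> list[Block]:
    """Keep blocks whose size reaches the minimal significant size."""
    if min_block < 1:
        raise ValueError("min_block must be >= 1")
    return [b for b in blocks if b.size >= min_block]
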