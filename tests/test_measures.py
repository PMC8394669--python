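"""Diagonal run-length measures against exhaustive line-scan oracles."""

import numpy as np
import pytest

from recurtrap.measures import (
    DetectionParams,
    DiagonalMeasures,
    block_times,
    candidate_blocks,
    diagonal_measures,
    filter_blocks,
)
from recurtrap.recurrence import BinaryRecurrenceMatrix
from recurtrap.trajectory_io import Block

from conftest import random_symmetric_binary


def oracle_measures(v: np.ndarray):
    """Exhaustive per-line run scan implementing the definitions directly."""
    n = len(v)
    t_block, t_perp, t_par = [], [], []
    for c in range(n):
        up = 0
        while c - up - 1 >= 0 and v[c - up - 1, c]:
            up += 1
        down = 0
        while c + down + 1 < n and v[c + down + 1, c]:
            down += 1
        t_block.append(up + down + 1)

        dl = 0  # down-left along the anti-diagonal
        while c + dl + 1 < n and c - dl - 1 >= 0 and v[c + dl + 1, c - dl - 1]:
            dl += 1
        ur = 0  # up-right
        while c - ur - 1 >= 0 and c + ur + 1 < n and v[c - ur - 1, c + ur + 1]:
            ur += 1
        t_perp.append(dl + ur + 1)

        r, s = c + dl, c - dl  # lower-left extremity
        fwd = 0
        while r + fwd + 1 < n and s + fwd + 1 < n and v[r + fwd + 1, s + fwd + 1]:
            fwd += 1
        back = 0
        while r - back - 1 >= 0 and s - back - 1 >= 0 and v[r - back - 1, s - back - 1]:
            back += 1
        t_par.append(fwd + back + 1)
    t_block = np.array(t_block)
    t_perp = np.array(t_perp)
    t_par = np.array(t_par)
    return t_block, t_perp, t_par, t_block / (t_par + t_perp - 1.0)


def _bin(v):
    return BinaryRecurrenceMatrix(np.asarray(v, dtype=np.uint8), 1.0, 0)


class TestDiagonalMeasures:
    @pytest.mark.parametrize("n", range(2, 51))
    def test_all_ones_invariant_is_one(self, n):
        """On an ideal full block, nu(n) = 1 at every diagonal position."""
        m = diagonal_measures(_bin(np.ones((n, n))))
        np.testing.assert_array_equal(m.nu, 1.0)

    def test_eight_step_full_block_values(self):
        """Hand evaluation at n=3 of a fully trapped 8-step matrix."""
        m = diagonal_measures(_bin(np.ones((8, 8))))
        assert m.t_block[2] == 8
        assert m.t_perp[2] == 5
        assert m.t_par[2] == 4
        assert m.nu[2] == 1.0

    @pytest.mark.parametrize("n", [5, 20, 41])
    def test_pure_diagonal_gives_one_over_n(self, n):
        """Ideal free motion: t_block = t_perp = 1, t_par = N, nu = 1/N."""
        m = diagonal_measures(_bin(np.eye(n)))
        np.testing.assert_array_equal(m.t_block, 1)
        np.testing.assert_array_equal(m.t_perp, 1)
        np.testing.assert_array_equal(m.t_par, n)
        np.testing.assert_allclose(m.nu, 1.0 / n)

    @pytest.mark.parametrize("s1", [5, 9, 15])
    @pytest.mark.parametrize("s2", [5, 11, 15])
    def test_adjacent_blocks_transition(self, s1, s2):
        """Two ideal blocks sharing one diagonal point: t_block at the
        transition is s1 + s2 - 1."""
        n = s1 + s2 + 10
        v = np.zeros((n, n))
        v[:s1, :s1] = 1
        v[s1 - 1 : s1 - 1 + s2, s1 - 1 : s1 - 1 + s2] = 1
        np.fill_diagonal(v, 1)
        m = diagonal_measures(_bin(v))
        assert m.t_block[s1 - 1] == s1 + s2 - 1
        assert m.nu[s1 - 1] < 1.0  # invariant broken at the transition

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("size,density", [(7, 0.5), (23, 0.3), (60, 0.6)])
    def test_matches_line_scan_oracle(self, seed, size, density):
        rng = np.random.default_rng(seed)
        B = random_symmetric_binary(size, density, rng)
        m = diagonal_measures(B)
        tb, tp, tl, nu = oracle_measures(B.values.astype(bool))
        np.testing.assert_array_equal(m.t_block, tb)
        np.testing.assert_array_equal(m.t_perp, tp)
        np.testing.assert_array_equal(m.t_par, tl)
        np.testing.assert_allclose(m.nu, nu)

    def test_time_reversal_symmetry_on_ideal_blocks(self):
        """Flipping the matrix on both axes reverses the measures."""
        n = 40
        v = np.zeros((n, n))
        v[5:17, 5:17] = 1
        v[25:33, 25:33] = 1
        np.fill_diagonal(v, 1)
        m = diagonal_measures(_bin(v))
        m_rev = diagonal_measures(_bin(v[::-1, ::-1]))
        np.testing.assert_array_equal(m_rev.t_block, m.t_block[::-1])
        np.testing.assert_array_equal(m_rev.t_perp, m.t_perp[::-1])
        np.testing.assert_allclose(m_rev.nu, m.nu[::-1])

    def test_zero_diagonal_rejected(self):
        v = np.eye(5)
        v[2, 2] = 0
        with pytest.raises(ValueError):
            diagonal_measures(_bin(v))

    def test_nu_bounds(self, rng):
        B = random_symmetric_binary(50, 0.4, rng)
        m = diagonal_measures(B)
        n = 50
        assert np.all(m.t_block >= 1) and np.all(m.t_block <= n)
        assert np.all(m.t_perp >= 1)
        assert np.all(m.t_par >= 1) and np.all(m.t_par <= n)
        assert np.all(m.nu > 0)


class TestBlockTimes:
    def test_zero_where_diagonal_is_zero(self):
        v = np.eye(6)
        v[3, 3] = 0
        tb = block_times(_bin(v))
        np.testing.assert_array_equal(tb, [1, 1, 1, 0, 1, 1])

    def test_agrees_with_measures_when_diagonal_full(self, rng):
        B = random_symmetric_binary(40, 0.35, rng)
        np.testing.assert_array_equal(block_times(B), diagonal_measures(B).t_block)


class TestCandidateBlocks:
    def _m(self, nu):
        nu = np.asarray(nu, dtype=float)
        one = np.ones_like(nu)
        return DiagonalMeasures(one, one, one, nu)

    def test_no_exceedance_gives_empty(self):
        assert candidate_blocks(self._m([0.1, 0.5, 0.75]), 0.75) == []

    def test_full_exceedance_gives_single_block(self):
        blocks = candidate_blocks(self._m(np.ones(12)), 0.75)
        assert [(b.start, b.end) for b in blocks] == [(1, 12)]

    def test_run_extraction(self):
        blocks = candidate_blocks(self._m([1.0, 1.0, 0.1, 1.0]), 0.75)
        assert [b.size for b in blocks] == [2, 1]

    def test_threshold_is_strict(self):
        assert candidate_blocks(self._m([0.75, 0.75]), 0.75) == []


class TestFilterBlocks:
    def test_keeps_blocks_at_least_min_size(self):
        blocks = [Block(1, 4), Block(10, 18), Block(30, 59)]
        kept = filter_blocks(blocks, 9)
        assert [b.size for b in kept] == [9, 30]

    def test_min_one_keeps_all(self):
        blocks = [Block(1, 1), Block(3, 4)]
        assert filter_blocks(blocks, 1) == blocks

    def test_empty_input(self):
        assert filter_blocks([], 5) == []


class TestMeasureProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20), size=st.integers(2, 40),
           density=st.floats(0.1, 0.9))
    def test_oracle_equivalence_property(self, seed, size, density):
        """The vectorized run-length measures equal the exhaustive scan on
        arbitrary symmetric unit-diagonal binary matrices."""
        rng = np.random.default_rng(seed)
        B = random_symmetric_binary(size, density, rng)
        m = diagonal_measures(B)
        tb, tp, tl, nu = oracle_measures(B.values.astype(bool))
        np.testing.assert_array_equal(m.t_block, tb)
        np.testing.assert_array_equal(m.t_perp, tp)
        np.testing.assert_array_equal(m.t_par, tl)
        np.testing.assert_allclose(m.nu, nu)


def test_detection_params_validation():
    with pytest.raises(ValueError):
        DetectionParams(lam=1.0, n_d=2, min_block=8, nu_c=1.5)
    with pytest.raises(ValueError):
        DetectionParams(lam=1.0, n_d=2, min_block=8, p_value=0.0)
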