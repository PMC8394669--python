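import numpy as np
import pytest

from recurtrap.recurrence import BinaryRecurrenceMatrix
from recurtrap.simulate import simulate_bm
from recurtrap.trajectory_io import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def bm_traj(rng):
    """A 300-step 2D Brownian trajectory."""
    return simulate_bm(300, 2, sigma=1.0, seed=rng)


@pytest.fixture
def small_traj():
    """Tiny deterministic 2D trajectory."""
    pos = np.array([[0.0, 0.0], [1.0, 0.5], [2.0, 0.2], [2.5, 1.0], [1.5, 1.2]])
    return Trajectory("t0", np.arange(1, 6), pos)


def random_symmetric_binary(n: int, density: float, rng) -> BinaryRecurrenceMatrix:
    """Random symmetric 0/1 matrix with unit diagonal."""
    v = (rng.random((n, n)) < density)
    v = (v | v.T).astype(np.uint8)
    np.fill_diagonal(v, 1)
    return BinaryRecurrenceMatrix(v, 1.0, 0)
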