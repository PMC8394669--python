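"""Trajectory simulators: Brownian, fractional Brownian, reflected trapped
motion, alternating free/trapped trajectories with ground truth, and
localisation noise.

The generators reproduce the benchmark conditions used throughout the
package: free motion with one-step lengthscale ``sigma = 1`` (diffusion
coefficient D = 1/2), subdiffusive fractional Brownian motion with Holder
exponent H = 0.35 (anomalous exponent alpha = 0.7) as a model of crowded
membranes, and trapping as reflected Brownian motion inside a disk (2D) or
sphere (3D). State durations alternate with Poisson-distributed lengths,
and imaging localisation error is modelled as additive white Gaussian
noise on every coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import Generator, default_rng

from .trajectory_io import Trajectory

__all__ = [
    "SimulationConfig",
    "LabelledTrajectory",
    "TAU_TRAP_RULE",
    "simulate_bm",
    "simulate_fbm",
    "simulate_trapped",
    "simulate_alternating",
    "add_noise",
    "fgn_autocovariance",
]

#: sentinel for the radius-dependent mean trapping duration 6 R^2 + 50
TAU_TRAP_RULE = "6R2+50"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of an alternating free/trapped simulation.

    Defaults mirror the benchmark conditions: 2D, 1000 steps, Brownian
    free motion with sigma = 1, mean free duration 20 frames, mean
    trapped duration 60 frames in a trap of radius 1, no noise.
    ``tau_trap`` may be the string "6R2+50", in which case the mean
    trapped duration is ``6 R^2 + 50`` for the drawn radius R.
    ``radius`` may be a (low, high) pair: each trap's radius is drawn
    uniformly from that range.
    """

    dim: int = 2
    n_steps: int = 1000
    free_model: str = "bm"  # "bm" | "fbm"
    hurst: float = 0.35
    sigma: float = 1.0
    tau_free: float = 20.0
    tau_trap: float | str = 60.0
    radius: float | tuple[float, float] = 1.0
    noise_sigma: float = 0.0
    dt: float = 0.5
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if self.free_model not in ("bm", "fbm"):
            raise ValueError("free_model must be 'bm' or 'fbm'")
        if not 0.0 < self.hurst < 1.0:
            raise ValueError("hurst must be in (0, 1)")
        if isinstance(self.tau_trap, str) and self.tau_trap != TAU_TRAP_RULE:
            raise ValueError(f"unknown tau_trap rule {self.tau_trap!r}")


@dataclass(frozen=True)
class LabelledTrajectory:
    """Simulated trajectory with per-frame ground truth.

    ``truth`` is boolean (True = trapped); ``traps`` lists
    (centre, radius, start, end) with 1-based inclusive frame endpoints.
    """

    trajectory: Trajectory
    truth: np.ndarray
    traps: tuple[tuple[np.ndarray, float, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        truth = np.asarray(self.truth, dtype=bool)
        if len(truth) != self.trajectory.n_points:
            raise ValueError("truth length must match trajectory length")
        object.__setattr__(self, "truth", truth)
        object.__setattr__(self, "traps", tuple(self.traps))


def _rng(seed) -> Generator:
    return seed if isinstance(seed, Generator) else default_rng(seed)


def simulate_bm(n_steps: int, dim: int = 2, sigma: float = 1.0, seed=None) -> Trajectory:
    """Brownian motion: i.i.d. Gaussian increments, per-coordinate std ``sigma``.

    ``sigma`` is the one-step diffusion lengthscale; D = sigma^2 / 2 per
    coordinate and frame.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = _rng(seed)
    incr = rng.normal(0.0, sigma, size=(n_steps - 1, dim))
    positions = np.vstack([np.zeros(dim), np.cumsum(incr, axis=0)])
    return Trajectory("bm", np.arange(1, n_steps + 1), positions)


def fgn_autocovariance(lags: np.ndarray, hurst: float, sigma: float = 1.0) -> np.ndarray:
    """Autocovariance of fractional Gaussian noise:
    ``gamma(k) = (sigma^2 / 2) (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})``."""
    k = np.abs(np.asarray(lags, dtype=np.float64))
    h2 = 2.0 * hurst
    return 0.5 * sigma * sigma * ((k + 1) ** h2 - 2 * k ** h2 + np.abs(k - 1) ** h2)


def _fgn(n: int, hurst: float, sigma: float, rng: Generator) -> np.ndarray:
    """Exact-covariance fractional Gaussian noise of length n.

    Davies-Harte circulant embedding; falls back to a Cholesky factor of
    the covariance matrix in the (rare, short-n) case of a negative
    circulant eigenvalue.
    """
    if n == 1:
        return rng.normal(0.0, sigma, size=1)
    gamma = fgn_autocovariance(np.arange(n + 1), hurst, sigma)
    # circulant first row: gamma_0 .. gamma_{n-1}, gamma_n, gamma_{n-1} .. gamma_1
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    m = len(row)  # 2n
    eig = np.fft.rfft(row).real
    if eig.min() < -1e-9 * eig.max():
        cov = fgn_autocovariance(np.abs(np.subtract.outer(np.arange(n), np.arange(n))),
                                 hurst, sigma)
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
        return L @ rng.normal(size=n)
    eig = np.clip(eig, 0.0, None)
    # hermitian-symmetric complex gaussian spectrum with variance eig * m / 2
    n_freq = len(eig)
    z = np.empty(n_freq, dtype=np.complex128)
    z[0] = rng.normal(0.0, np.sqrt(eig[0] * m))
    z[-1] = rng.normal(0.0, np.sqrt(eig[-1] * m))
    interior = np.sqrt(eig[1:-1] * m / 2.0)
    z[1:-1] = interior * (rng.normal(size=n_freq - 2) + 1j * rng.normal(size=n_freq - 2))
    x = np.fft.irfft(z, n=m)
    return x[:n]


def simulate_fbm(
    n_steps: int, dim: int = 2, hurst: float = 0.35, sigma: float = 1.0, seed=None
) -> Trajectory:
    """Fractional Brownian motion, one independent exact fGn per coordinate.

    ``hurst`` is the Holder exponent H; the ensemble MSD grows as
    ``n^(2H)`` (anomalous exponent alpha = 2H). H = 0.5 reduces to
    Brownian motion.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must be in (0, 1)")
    rng = _rng(seed)
    incr = np.column_stack([_fgn(n_steps - 1, hurst, sigma, rng) for _ in range(dim)])
    positions = np.vstack([np.zeros(dim), np.cumsum(incr, axis=0)])
    return Trajectory("fbm", np.arange(1, n_steps + 1), positions)


def _uniform_in_ball(n: int, dim: int, radius: float, rng: Generator) -> np.ndarray:
    v = rng.normal(size=(n, dim))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / dim)
    return v * r[:, None]


def _reflect_into_ball(x: np.ndarray, centre: np.ndarray, radius: float) -> np.ndarray:
    """Radial mirror reflection of points that left the ball."""
    d = x - centre
    r = np.linalg.norm(d)
    while r > radius:
        d = d * ((2.0 * radius - r) / r)
        r = abs(2.0 * radius - r)
    return centre + d


def simulate_trapped(
    n_steps: int,
    dim: int = 2,
    radius: float = 1.0,
    sigma: float = 1.0,
    dt: float = 0.5,
    centre=None,
    seed=None,
) -> Trajectory:
    """Motion confined to a disk/sphere of given radius.

    Reflected Brownian motion integrated with sub-steps of duration
    ``dt`` (reflection at the boundary), sampled once per frame. When the
    per-sub-step diffusion length exceeds a third of the radius
    (``sqrt(2 D dt) > R / 3``), the reflected walk decorrelates within a
    frame and positions are instead drawn i.i.d. uniform in the trap —
    the stationary distribution of reflected Brownian motion.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = _rng(seed)
    centre = np.zeros(dim) if centre is None else np.asarray(centre, dtype=float)
    positions = _trapped_positions(n_steps, dim, radius, sigma, dt, centre, rng)
    return Trajectory("trapped", np.arange(1, n_steps + 1), positions)


def _trapped_positions(
    n_steps: int, dim: int, radius: float, sigma: float, dt: float,
    centre: np.ndarray, rng: Generator,
) -> np.ndarray:
    D = sigma * sigma / 2.0
    if np.sqrt(2.0 * D * dt) > radius / 3.0:
        return centre + _uniform_in_ball(n_steps, dim, radius, rng)
    n_sub = max(1, round(1.0 / dt))
    positions = np.empty((n_steps, dim))
    x = centre.copy()
    step_sd = sigma * np.sqrt(dt)
    for i in range(n_steps):
        for _ in range(n_sub):
            x = _reflect_into_ball(x + rng.normal(0.0, step_sd, dim), centre, radius)
        positions[i] = x
    return positions


def _poisson_duration(mean: float, rng: Generator) -> int:
    """Poisson-distributed duration in frames; zero draws redrawn as 1
    (a zero-length state would be a no-op in the alternation)."""
    d = int(rng.poisson(mean))
    return max(d, 1)


def _draw_radius(radius, rng: Generator) -> float:
    if np.isscalar(radius):
        return float(radius)
    lo, hi = radius
    return float(rng.uniform(lo, hi))


def simulate_alternating(config: SimulationConfig, seed=None) -> LabelledTrajectory:
    """Trajectory alternating free and trapped states, with ground truth.

    Starts in the free state. Segment durations are Poisson with means
    ``tau_free`` / ``tau_trap`` (or 6 R^2 + 50 when the rule is selected).
    Each trap is centred at the particle position on entry; the free
    segment after a trap resumes from the last trapped position. With
    ``tau_trap == 0`` the trajectory is entirely free (the no-trapping
    control regime). fBm free segments are generated independently per
    segment. Noise, if any, is added after ground truth is recorded.
    """
    rng = _rng(seed)
    n = config.n_steps
    dim = config.dim

    use_rule = isinstance(config.tau_trap, str)
    if not use_rule and config.tau_trap == 0:
        traj = _free_segment(n, config, rng, start=np.zeros(dim))
        labelled = LabelledTrajectory(
            Trajectory("alt", np.arange(1, n + 1), traj, config.frame_interval),
            np.zeros(n, dtype=bool),
        )
        return _with_noise(labelled, config, rng)

    positions = np.empty((n, dim))
    truth = np.zeros(n, dtype=bool)
    traps: list[tuple[np.ndarray, float, int, int]] = []
    pos = np.zeros(dim)
    i = 0
    free = True
    while i < n:
        if free:
            d = min(_poisson_duration(config.tau_free, rng), n - i)
            seg = _free_segment(d, config, rng, start=pos)
            positions[i : i + d] = seg
        else:
            radius = _draw_radius(config.radius, rng)
            tau = 6.0 * radius * radius + 50.0 if use_rule else float(config.tau_trap)
            d = min(_poisson_duration(tau, rng), n - i)
            positions[i : i + d] = _trapped_positions(
                d, dim, radius, config.sigma, config.dt, pos, rng
            )
            truth[i : i + d] = True
            traps.append((pos.copy(), radius, i + 1, i + d))
        pos = positions[i + d - 1].copy()
        i += d
        free = not free
    labelled = LabelledTrajectory(
        Trajectory("alt", np.arange(1, n + 1), positions, config.frame_interval),
        truth,
        traps,
    )
    return _with_noise(labelled, config, rng)


def _free_segment(d: int, config: SimulationConfig, rng: Generator, start: np.ndarray) -> np.ndarray:
    """d positions of free motion whose first point continues from ``start``
    by one free increment."""
    dim = config.dim
    if config.free_model == "fbm" and d > 1:
        incr = np.column_stack([_fgn(d, config.hurst, config.sigma, rng) for _ in range(dim)])
    else:
        incr = rng.normal(0.0, config.sigma, size=(d, dim))
    return start + np.cumsum(incr, axis=0)


def _with_noise(labelled: LabelledTrajectory, config: SimulationConfig, rng: Generator):
    if config.noise_sigma == 0:
        return labelled
    noisy = add_noise(labelled.trajectory, config.noise_sigma, seed=rng)
    return LabelledTrajectory(noisy, labelled.truth, labelled.traps)


def add_noise(traj: Trajectory, noise_sigma: float, seed=None) -> Trajectory:
    """Add i.i.d. Gaussian localisation error of std ``noise_sigma`` to
    every coordinate of every frame."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return traj
    rng = _rng(seed)
    noisy = traj.positions + rng.normal(0.0, noise_sigma, size=traj.positions.shape)
    return Trajectory(traj.id, traj.frames, noisy, traj.frame_interval)
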