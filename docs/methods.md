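# Methods

This note records the model, the numerical choices and the limitations of
`recurtrap`, in the package's own words. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Model and procedure

A trajectory is an ordered sequence of `N ≥ 2` positions in 2 or 3
dimensions. Before any analysis the one-step increments of each coordinate
are rescaled by their sample standard deviation (mean subtracted, `ddof=1`
over the `N−1` increments) and re-accumulated from the original first
position. Detection results are therefore independent of the diffusion
coefficient and of length units; the test lengthscale λ is expressed in
units of the one-step displacement scale. A stuck particle (zero increment
variance) is rejected as degenerate. Whether the increment mean should be
subtracted is immaterial for diffusive data (the mean is `O(σ/√N)`); we
subtract it because it is the standard estimator.

The pipeline to the binary matrix `B` is fixed:

1. **Recurrence matrix** `M_ij = exp(−(|x_i−x_j|/λ)²/2)`, computed via the
   Gram-matrix identity `|x_i−x_j|² = |x_i|² + |x_j|² − 2 x_i·x_j` (BLAS),
   symmetrized by taking the entrywise minimum with its transpose to kill
   round-off asymmetry, unit diagonal forced. Weights below `1e-20` are
   flushed to exact zero: they are 18 orders of magnitude below anything
   the threshold can see, and subnormal entries would slow the smoother by
   an order of magnitude.
2. **Smoothing** by the mean over a `(2μ+1)×(2μ+1)` window, default μ = 2.
   Border windows are normalized by the number of in-bounds cells
   (edge-corrected mean); a zero-padded mean would suppress `B` near the
   trajectory endpoints and shrink first/last blocks. The default path uses
   a separable moving sum; an FFT convolution path is kept and both are
   tested against the direct windowed mean to 1e-10.
3. **Threshold** at `p_c = e⁻¹`, strictly (`>`): two frames colocalize when
   their unsmoothed weight exceeds `e⁻¹`, i.e. within distance `λ√2`.
4. **Hole filling**: 0-regions (4-connected) not touching the matrix border
   are set to 1. Holes are punched into blocks by brief excursions during a
   trapping event; filling restores the block before measuring. Filling is
   applied to the whole matrix — off-diagonal components are symmetric
   copies and do not affect the diagonal measures. Implemented by labelling
   the zero set and keeping components that reach the border; the
   classical border flood-fill serves as the test oracle.
5. **Diagonal banding**: all entries with `|i−j| ≤ n_d` are set to 1.

## The three measures and the invariant

At each diagonal position `n` (1-based, matching frame numbering), three
maximal runs of ones through `B_nn` are measured, truncated at the matrix
border, no wrap-around:

* `t|(n)` — vertical run (the apparent trapping duration seen from `n`);
* `t⊥(n)` — anti-diagonal run, counted on **both** sides of `(n,n)`;
* `t‖(n)` — run parallel to the main diagonal through the lower-left
  extremity of the `t⊥` run, counted in both directions. By symmetry of
  `B` the upper-right extremity gives the same value.

The invariant `ν(n) = t|/(t‖ + t⊥ − 1)` equals 1 at every diagonal position
of an all-ones matrix: with `m = min(n, N+1−n)`, `t| = N`, `t⊥ = 2m−1` and
the extremity lies on a diagonal of length `N − 2m + 2`, so the denominator
telescopes to `N`. This two-sided reading of `t⊥` and `t‖` is the unique
one under which the identity is exact (e.g. `8 = 4 + 5 − 1` at `n = 3`,
`N = 8`); a one-sided reading breaks it. On an ideal free (banded) matrix
interior points give `ν = (2n_d+1)/N`, and at the junction of two ideal
blocks of sizes `s₁, s₂` sharing one diagonal point the vertical run is
`s₁ + s₂ − 1` while the persistence run explodes, which is what makes block
transitions sharp once the band is added.

The implementation indexes runs from the sparse coordinate list of 1-cells
(sort by line id and position, break runs where positions jump), which is
`O(m log m)` in the number of 1-cells instead of `O(N²)` dense passes; an
exhaustive per-line scan is kept in the test suite as the oracle.

Frames with `ν > ν_c` (strict; default `ν_c = 3/4`, tolerating deformed
blocks) form candidate blocks; blocks shorter than the calibrated minimal
significant size are rejected.

## Calibration

Free motion also produces blocks, because escaping a region of size λ takes
a random time. Two thresholds are calibrated per (reference model,
dimension, λ, μ), against simulated standardized reference trajectories
(Brownian, or fBm with H = 0.35):

* **Band count `n_d`** — the nearest-rank 10th percentile of `t|` pooled
  over all frames of all reference trajectories, with the pipeline run
  through hole filling but without banding. Frames whose diagonal entry
  does not survive thresholding carry no block time and are excluded from
  the pool: the run-length definition presumes `B_nn = 1`, and for 2D
  Brownian motion at λ = 1 about one frame in seven falls in this state —
  counting them as zeros would collapse the percentile to zero and leave
  free-motion ν high, visibly inflating the false-positive rate on
  trap-free data.
* **Minimal significant size `τ_pval`** — run the *full* pipeline
  (including banding with the `n_d` just calibrated, so that the null
  statistic matches the statistic being thresholded), pool all candidate
  block sizes, and take the smallest size whose empirical CDF reaches
  `1 − p_val` (default `p_val = 0.05`). `τ` is non-increasing in the
  p-value and non-decreasing in λ.

Reference scale defaults match the full study (10³ trajectories; 2×10³
steps for the band stage, 10⁴ for the null stage); reduced scales are
first-class configuration. The desk-scale runs used by the acceptance
script are 100×1000 (band stage), 200×2000 (null, λ = 1) and 100×4000
(null, λ = 3 — longer trajectories because null blocks grow with λ, fewer
of them because the pipeline cost grows as `N²`; the quantile is a
per-block statistic, so what matters is the pooled block count, which is
comparable in the two runs). Calibration tables persist to JSON and reload
bit-identically.

## Simulators

* **Brownian motion**: i.i.d. Gaussian increments, per-coordinate std σ
  (default 1, i.e. `D = σ²/2 = 1/2` per coordinate and frame).
* **Fractional Brownian motion**: independent exact-covariance fractional
  Gaussian noise per coordinate, synthesized by Davies–Harte circulant
  embedding (Cholesky fallback if an eigenvalue of the embedding is
  negative, which does not occur for fGn at the sizes used). The contract
  is the closed-form increment autocovariance
  `γ(k) = (σ²/2)(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})`, tested directly.
  Default H = 0.35 (anomalous exponent α = 0.7), a model of diffusion in
  crowded media.
* **Trapped motion**: reflected Brownian motion in a disk/sphere of radius
  `R`, integrated with sub-steps `dt = 1/2` and radial mirror reflection,
  sampled once per frame. When the sub-step diffusion length exceeds `R/3`
  (`√(2D·dt) > R/3`) the walk decorrelates within a frame and positions
  are drawn i.i.d. uniform in the trap instead — the stationary law of
  reflected Brownian motion. With σ = 1, `dt = 1/2`, this uniform
  approximation is active for `R < 3/√2 ≈ 2.12`.
* **Alternating trajectories**: start free; segment durations are Poisson
  with means `τ_free` / `τ_trap` (zero draws redrawn as 1 — a zero-length
  state is a no-op in the alternation); `τ_trap` may follow the
  radius-dependent rule `6R² + 50`. Trap radii are drawn uniformly when a
  range `[1, R_max]` is given. Each trap is centred at the entry position
  and the next free segment resumes from the last trapped position, so
  paths are continuous. fBm free segments are generated independently per
  segment (no memory across trapping events). Ground-truth labels and trap
  geometry are recorded before localisation noise — i.i.d. Gaussian,
  std `σ_err` per coordinate — is added.

What the generator does *not* emulate: tracking gaps and misconnections,
blinking, heavy-tailed localisation error, drift, hop diffusion between
adjacent compartments (approximable by small `τ_free`), or fBm memory
persisting across traps. Passing benchmarks therefore demonstrate
correctness of the detector under the stated generative model, not
robustness to every artefact of real SPT data.

## Detection defaults and scoring

Defaults mirror the experimental analysis the method was designed for:
λ ∈ {0.5, 1, 1.5, 2}, μ = 2, `ν_c = 3/4`, `p_val = 0.05`, fBm reference
(conservative null for membrane data); the Brownian reference is
selectable and is what the simulation benchmarks use. Multi-λ detection
takes the union of trapped frames across lengthscales; merged blocks carry
no λ tag. Trajectories shorter than `τ_pval` return all-free with a
warning — detection is impossible at that lengthscale.

The recognition score is the fraction of frames whose predicted binary
state matches ground truth, averaged over trajectories — the simplest
frame-level reading of "trajectories correctly assigned to their state"
with a [0,1] range. The benchmark grid reports its mean per simulation
cell.

## TAMSD and trap geometry

`δ²(n)` is computed per coordinate by the standard time average and summed
over coordinates; the fit `δ²(n) = 2·dim·(D_α n^α + σ_err²)` (= `4D_α n^α +
4σ_err²` in 2D) over lags 1–5 uses bounded nonlinear least squares
(`D_α > 0`, `α ∈ (0, 4]`, `σ_err ≥ 0`) multi-started at α ∈ {0.5, 1.0, 1.5},
because a 3-parameter power law on 5 points is ill-conditioned; the best
residual wins and non-convergence is flagged, not raised. The fit is
unweighted. Free portions shorter than 50 frames are excluded from TAMSD
analysis. Trap radius is the nearest-rank 95th percentile of distances to
the coordinate-wise median centre (even counts: midpoint convention) — the
"point further away than 95% of points". This radius is exactly
translation-invariant but only approximately rotation-invariant, since the
coordinate-wise median is not rotation-equivariant; tests assert 5%
agreement under rotation.

## Numerical choices and degenerate inputs

* Strict inequalities at both thresholds (`> p_c`, `> ν_c`), per their
  definitions.
* Nearest-rank percentiles everywhere integers are involved
  (band count, `τ_pval`, trap radius): deterministic on discrete data.
* All run lengths truncate at matrix borders; no wrap-around.
* Seeding: every stochastic routine accepts a seed or Generator;
  multi-stage procedures split streams with `SeedSequence.spawn`, so
  calibration stages and benchmark cells are independent and reproducible.
* Degenerate inputs: `2μ+1 > N` is a parameter error; zero increment
  variance is a degenerate-trajectory error; an empty null ECDF is a
  calibration error; a null ECDF that never reaches `1 − p_val` returns
  (largest observed size + 1), i.e. conservatively rejects nothing smaller
  than anything ever seen under the null.

## Known limitations

* Dense `N×N` matrices: memory is `O(N²)` (≈130 MB at `N = 4000`);
  trajectories beyond ~10⁴ frames need chunking that v1 does not provide.
* The null calibration is purely empirical; no analytic approximation of
  the block-size distribution is attempted.
* Detection quality degrades, by construction, when trapping durations are
  close to or below `τ_pval`, or when free excursions between traps are
  shorter than the time to diffuse out of the test lengthscale.
* The uniform-fill approximation inside small traps discards within-trap
  temporal correlation; at the frame rate and radii used this correlation
  is negligible, but analyses of sub-frame dynamics should not rely on it.
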