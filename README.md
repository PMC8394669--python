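# recurtrap

Detection of **transient trapping events** inside individual 2D/3D
single-particle trajectories, based on block structures of a smoothed
recurrence matrix.

Membrane proteins tracked by single-molecule microscopy alternate between
free lateral diffusion and transient confinement in nano-domains. Analysing
such trajectories with a single-motion model misreads this intermittency as
anomalous diffusion. `recurtrap` segments each trajectory, on its own, into
*free* and *trapped* portions — without sliding windows, without requiring
multiple visits to the same domain, and with an explicit statistical control
against false detections. It is aimed at single-particle-tracking
practitioners (e.g. GPCR imaging) and at method developers who need a
calibrated confinement detector and matching simulators.

## Method

For a trajectory `x_1 … x_N` (increments standardized to unit variance per
coordinate), a recurrence matrix with Gaussian weights is built at a test
lengthscale λ:

    M_ij = exp( -(|x_i - x_j| / λ)² / 2 )

`M` is box-smoothed (window `(2μ+1)²`, default μ = 2), thresholded at
`p_c = e⁻¹`, holes inside diagonal blocks are filled, and `n_d` diagonal
lines are forced to 1 on each side of the diagonal. A trapping event of
size ≈ λ appears as a square block of ones on the diagonal of the binary
matrix `B`. At every diagonal position `n` three run lengths are measured —
block time `t|` (vertical run through `B_nn`), neighbouring time `t⊥`
(anti-diagonal run) and persistence time `t‖` (run parallel to the diagonal
through the extremity of the `t⊥` segment) — and combined into the block
invariant

    ν(n) = t|(n) / ( t‖(n) + t⊥(n) - 1 )

which equals 1 at every point of an ideal block and collapses towards
`(2 n_d + 1)/N` on free stretches. Frames with `ν > ν_c` (default 3/4) form
candidate blocks. Both `n_d` (10th percentile of null block times) and the
minimal significant block size `τ_pval` (95% quantile of null candidate
block sizes at p = 0.05) are calibrated by Monte-Carlo simulation of a
reference free motion — Brownian, or subdiffusive fractional Brownian
motion (H = 0.35) for crowded membranes. Detections at several λ are
combined by taking the union of trapped frames.

Post-analysis utilities summarise segmented data: robust trap radii
(95th-percentile distance from the coordinate-wise median centre), trapping
durations, per-cell trapped fractions, and TAMSD fits
`δ²(n) = 4 D_α n^α + 4 σ_err²` over lags 1–5 for free portions.

## Worked example

```python
import numpy as np
from recurtrap import (SimulationConfig, simulate_alternating,
                       calibrate_entry, DetectionParams,
                       detect_single_scale, recognition_score)

# calibrate against a 2D Brownian reference at lambda = 1 (desk scale)
entry = calibrate_entry("bm", 2, 1.0, mu=2,
                        n_traj_band=100, n_steps_band=1000,
                        n_traj_null=200, n_steps_null=2000, seed=0)
print(entry.n_d, entry.min_block(0.05))
# 2 8     -> add 2 diagonal lines; blocks shorter than 8 frames are chance

# simulate a trajectory alternating free diffusion and trapping (R = 1)
cfg = SimulationConfig(n_steps=1000, tau_free=20, tau_trap=60,
                       radius=1.0, noise_sigma=0.1)
lab = simulate_alternating(cfg, seed=1)

params = DetectionParams(lam=1.0, n_d=entry.n_d, min_block=entry.min_block(0.05))
res = detect_single_scale(lab.trajectory, params)
print(len(res.blocks), round(recognition_score(res.labels, lab.truth), 3))
# 13 0.953  -> 13 trapping events found; 95.3% of frames labelled correctly
```

The same pipeline is available from the shell:

```sh
recurtrap calibrate --model bm --dim 2 --lambdas 1.0 --seed 0 --out cal.json
recurtrap simulate --n-traj 10 --seed 1 --out traj.csv --truth-out truth.csv
recurtrap detect --input traj.csv --lambdas 1 --reference bm \
                 --calibration cal.json --out labels.csv
recurtrap analyze --input traj.csv --labels labels.csv --out-prefix results
```

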