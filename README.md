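# famotion

Quantitative analysis of how a soluble growth-factor stimulus (EGF) shapes
cell migration through focal-adhesion and protrusion dynamics.

`famotion` links the three data streams of a live-cell EGF dose-response
imaging experiment into one comparison:

* **centroid tracks** (phase contrast, minutes-scale) → per-cell migration
  speed `S` and directional persistence time `P` from a persistent random
  walk fit;
* **TIRF movies** of a fluorescent focal-adhesion marker (e.g.
  paxillin-EGFP, seconds-scale) → per-adhesion intensity, area, elongation,
  sliding speed, lifetime and per-frame adhesion counts per cell;
* **cell-mask movies** → sector × time edge-velocity maps and
  traveling-protrusion-wave metrics.

Cells are then grouped either by EGF dose — no (0 nM), low (0.01, 0.1 nM),
high (1, 10, 100 nM) — or by migration speed (slow/fast at a data-derived
2-means cutoff), and each characteristic's between-group difference is
scored with the Kolmogorov–Smirnov statistic. Because the microscopy data
this kind of study rests on are rarely deposited, the package ships a
first-class synthetic-data generator producing all three streams with known
ground truth, so every stage is validated by parameter recovery.

## The models

**Migration.** A cell performing a persistent random walk with RMS speed
`S` and persistence time `P` has ensemble mean squared displacement

```
MSD(t) = 2 S² P (t − P(1 − e^(−t/P)))
```

`PRWModel.fit()` estimates `(S, P)` by nonlinear least squares on the
non-overlapping-interval MSD up to a 30-min lag (multi-start over P).
The simulator is the exact generative counterpart: an Ornstein–Uhlenbeck
velocity process with stationary speed variance `S²` and correlation time
`P`, integrated with its exact Gaussian transition, so the formula above
holds in expectation at every lag.

**Distribution comparison.** Between-group differences are measured by the
two-sample KS statistic `D = sup |F_a − F_b|` (averaged over the three
pairwise comparisons for the three EGF groups), and parametric families
(lognormal; Weibull for sliding speed; Gaussian for edge velocities) are
fitted by minimizing the one-sample KS distance.

**Protrusion waves.** The cell edge is divided into 100 angular sectors;
per-sector signed normal edge velocity over time forms an `EdgeMap`.
A laterally traveling wave appears as a best-correlation sector offset that
grows linearly with temporal lag; the slope is the wave speed in
sectors/frame.

## Worked example

```python
import famotion as fm

# simulate 50 cells migrating at S = 40 um/hr with P = 0.2 hr,
# sampled every 2 min for 8 h, then fit the PRW model to one cell
tracks = fm.simulate_prw_tracks(
    fm.PRWParams(speed=40, persistence=0.2, n_cells=50, seed=1))
res = fm.PRWModel.from_trajectory(tracks[0]).fit(max_fit_lag=30)
print(res.summary())
```

```
Persistent random walk MSD fit
==============================================
cell id:             0
lags used:           15 (<= 30 min)
speed S:                 40.678 um/hr
persistence P:           0.2217 hr  (13.30 min)
residual SS:               1199 um^4
residual RMSE:            8.939 um^2
converged:           True
identifiability:     ok
```

A single cell's fitted speed scatters around the simulated 40 um/hr (this
one lands at 40.7; others stray by 10-30%) because one 8-h track carries
limited information; the population median over the 50 cells recovers `S`
closely:

```python
import numpy as np
speeds = [fm.PRWModel.from_trajectory(t).fit().speed for t in tracks]
part = fm.kmeans_speed_cutoff(speeds)     # exact 1-D 2-means
print(f"{np.median(speeds):.1f} um/hr median, cutoff {part.cutoff:.1f}")
# -> 40.0 um/hr median, cutoff 39.3
```

The full workflow — simulate a six-dose condition dataset, segment and
track adhesions, map protrusion, compare groups — runs from a single
config:

```bash
famotion run --seed 1 --out-dir results/
```

which writes per-stage CSV tables and a JSON report containing, per
characteristic, the averaged pairwise KS under both grouping schemes,
KS-minimization distribution fits, and group means with Welch-test flags
(p < 0.01).

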