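# Methods

This note records the models, conventions, numerical choices and known
limitations behind `famotion`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
imported from external data.

## Persistent random walk migration model

Cell centroid tracks are summarized by the mean squared displacement
constructed from **non-overlapping** time intervals: for a track of N steps
at sampling interval dt, the lag k·dt uses the floor(N/k) displacements
(0→k, k→2k, ...). Non-overlapping intervals keep the per-lag displacement
counts independent; lags with a single displacement are retained.

The persistent random walk (PRW) model

    MSD(t) = 2 S² P (t − P (1 − e^(−t/P)))

is fitted by unweighted nonlinear least squares to lags ≤ 30 min (beyond
that, 2-min sampling of 6–8 h tracks leaves too few non-overlapping
displacements). The objective is multimodal in P, so the fit restarts from
P ∈ {1, 2, 5, 10, 20, 60} min with the conditionally optimal S each time
and keeps the best optimum. When the fitted P falls below one sampling
interval or beyond the fitted lag window, S and P are not separately
identifiable (only the diffusivity S²P, or the ballistic speed, is
constrained); the fit then carries an `identifiability_flag` rather than
an error. Internal units are µm and minutes; S is reported in µm/hr and P
in hours — a reporting convention, since persistence times near 0.1–0.3 hr
could equally be quoted in minutes.

The simulator is the exact generative counterpart: each velocity component
is a stationary Ornstein–Uhlenbeck process with variance S²/2 and
correlation time P, and positions are advanced with the exact joint
(position, velocity) Gaussian transition over each sampling step — no
Euler discretization bias, so the ensemble MSD matches the formula above
at every lag in expectation. Verified: at S = 40 µm/hr, P = 0.2 hr,
n = 200 cells, every lag ≤ 30 min agrees with the closed form within 3
standard errors; median parameter recovery over S ∈ {20, 40, 80} µm/hr ×
P ∈ {0.1, 0.3} hr at 50 cells per condition is within 2% for S and 8% for
P.

**Speed partition.** Cells are split into slow/fast groups by 2-means
clustering of the fitted speeds. In one dimension the optimal 2-means
partition is a split of the sorted sample, so the global optimum is found
by exhaustive search over the n−1 sorted splits — deterministic, unlike
Lloyd iterations. The cutoff is the midpoint of the inter-cluster gap (the
placement of a single reported cutoff number is otherwise ambiguous);
among numerically tied splits the widest gap wins.

## Focal-adhesion movie generator

Adhesions are rendered as anisotropic 2-D Gaussian spots on a dim
disk-shaped cell footprint over a constant background with additive
Gaussian read noise (Poisson shot noise deliberately out of scope). The
**area** of an adhesion is defined as the region above half of its peak
("half-maximum convention"): for a Gaussian with principal sigmas σ₁, σ₂
that ellipse has area 2π ln2 σ₁σ₂, the mean intensity over it is
peak/(2 ln2), and the elongation is σ₁/σ₂. These closed forms are the
ground truth the segmentation is tested against.

Lifetimes are drawn per adhesion (default exponential, mean 300 s, at 10-s
frames); intensity follows a trapezoidal assembly/plateau/disassembly
profile (ramps over the first and last quarter of life) or a flat profile;
centroids slide at a per-adhesion speed in a fixed random direction.
Photobleaching is a global per-frame fractional decay, default 0 (typical
experiments are checked to lose little intensity; the QC stage measures
exactly this). An initial population with uniformly distributed ages makes
frame 0 statistically stationary; adhesions touching the first or last
frame are flagged censored. A movie whose expected adhesion footprint
exceeds a quarter of the cell area records an overlap warning in its
metadata. `min_separation_um` optionally enforces a minimum spacing between
adhesions, checked along their whole slide paths so adhesions cannot
drift into each other mid-movie (rejection sampling); 0 disables it.

Defaults: 0.16 µm/px (a convention — the experimental pixel size is
unpublished), 10-s frames, 16-bit grayscale, background 400, cell plateau
+600, peak intensities lognormal (median 8000, σ_log 0.4), areas lognormal
(median 1 µm², σ_log 0.5), sliding speeds lognormal (median 8 µm/hr),
elongations uniform 1.2–2.5.

## Adhesion segmentation and measurement

The published pipelines this mirrors delegate their operators to cited
tools, so the recipe here is the package's own, chosen so that every step
has an analytically checkable effect on the Gaussian-spot ground truth:

1. **Cell mask**: the frame is smoothed (σ = 1.2 µm); the background level
   is anchored on the image border strip (lower quartile — the cell is
   assumed not to fill the field of view), the foreground level is the
   modal smoothed intensity clearly above background (the histogram peak
   tracks the cytoplasmic plateau and ignores both the boundary ramp and
   bright adhesion halos), and the threshold is their midpoint, which
   recovers a blur-smeared step boundary at its true position. Largest
   component, holes filled. Frames without contrast above the smoothed
   noise level, or without a plausibly cell-sized component (≥ 20 µm²),
   yield an empty mask with a warning. All statistics are relative, so the
   mask is invariant to rescaling the frame. A 10-µm disk is recovered
   within 2% of its area. Limitation: a cell touching the border corrupts
   the background anchor.
2. **Background subtraction**: normalized convolution (σ = 2 µm) over
   in-cell pixels only; then a second pass excluding the detected
   adhesions, because a spot's own mass in the background estimate would
   subtract a hump under the spot and shrink its half-maximum region
   (~15% area bias in the single-pass variant).
3. **Detection**: threshold at 6× the noise surviving a σ = 1 px
   pre-smoothing (a matched-filter-like step; typical adhesion peaks sit
   9× or more above it, while noise-blob detections per movie stay near
   zero). Touching spots are split by
   watershed seeded from h-maxima with prominence 4× the smoothed noise —
   noise wiggles on one spot do not split it, genuinely separate peaks do.
4. **Sizing**: each spot is re-delineated at half of its own peak on a
   σ = 2 px smoothed field (stable boundaries under noise). The smoothing
   widens the half-maximum ellipse by a known amount, removed analytically:
   the semi-axis product comes from the region pixel count, the axis ratio
   from region moments, and 2 ln2 σ² is subtracted per squared semi-axis.
   The measured peak is corrected by −0.5σ_noise (the max of a correlated
   field over one spot overshoots by about half a sd). Mean intensity is
   measured on the raw background-subtracted frame over the region and
   rescaled to the exact half-maximum convention using the known region/
   area ratio. Components whose corrected area is below 3 px are removed
   (sub-resolution detections); tracks with time-averaged area outside
   [0.05, 10] µm² are excluded, boundaries inclusive (below: unresolved;
   above: likely clusters of several adhesions).
5. **Tracking**: frame-to-frame greedy assignment by maximal pixel
   overlap, falling back to nearest centroid within 1 µm/frame; ties break
   toward the smaller area change; one-frame gaps are closed (gap frames
   carry interpolated centroids and NaN measurements). Centroids are
   intensity-weighted — binary centroids of small rasterized regions
   jitter by a sizeable fraction of a pixel.
6. **Sliding speed** is the length-weighted mean of linear-fit velocities
   over windows of ≤ 15 frames, with the localization-jitter contribution
   to the squared speed subtracted using the fit residuals. Naive
   frame-to-frame differencing is hopeless here: a typical 8 µm/hr slide
   moves 0.14 px per 10-s frame, well below the localization noise, and
   the mean step length would be biased upward several-fold. For straight
   constant-speed motion the windowed fit equals the frame-to-frame mean
   exactly.
7. **Lifetime** is (last − first + 1) × frame interval, a declared
   convention; censored tracks are excluded from lifetime distributions
   but keep their other properties. **FA number per cell** is the
   per-frame count of filtered adhesions; the full per-frame sequence
   (not its mean) forms the number-per-cell distribution, so its
   measurement count is (frames × cells).

**Verified recovery** (synthetic movies, well-separated regime = 2.5 µm
minimum spacing): noise-free flat-profile movies give per-frame counts
exactly equal to ground truth and one-to-one track identity; at moderate
noise — defined as a typical adhesion's mean fluorescence signal at 5× the
pixel noise sd (noise 860 on 16-bit counts with the default intensity
distribution) — the recovered distributions of area, mean intensity,
uncensored lifetime and sliding speed are each within KS 0.1 of ground
truth at n ≥ 200 adhesions. Known residual biases at that noise: area +6–8%, mean intensity −3%. With the trapezoidal profile, frames whose
ramp amplitude falls below the detection threshold shorten apparent
lifetimes; recovery tests therefore use the flat profile, which isolates
segmentation fidelity from that detectability censoring (condition
datasets keep the trapezoid default — group orderings are unaffected).
Dense fields where adhesions overlap merge into single detections, as in
real imagery; the area filter's upper bound is precisely the guard against
such clusters.

## Protrusion mapping

Contours are extracted at the 0.5 level of the mask (marching squares)
with a light 5-point circular smoothing that removes the half-pixel
staircase (otherwise perimeters inflate ~8%). Sectors are angular bins
around a single fixed reference centroid (the mean of per-frame mask
centroids), so a sector indexes the same edge region in every frame; the
per-sector velocity is the change of mean sector radius per frame
interval, outward positive, in µm/min. This construction assumes a
star-shaped cell; strongly concave outlines fold multiple edge segments
into one sector and the map becomes an average over them. A uniformly
dilating disk (0.2 µm/min) is recovered within 10% in every sector;
mean sector velocity × perimeter tracks dA/dt within 10%.

**Wave detection.** For temporal lags τ = 1..8 the lateral offset (up to a
quarter circumference, both directions) maximizing the spatiotemporal
correlation is found on a temporally moving-averaged copy of the map
(window 5; edge-measurement jitter is white in time while a wave is
coherent, so the averaging is a matched filter — the reported velocity
std uses the raw map). A wave is declared when the best offset grows
linearly with τ (R² > 0.8) and the lag-1 peak correlation exceeds 0.4;
the slope is the wave speed in sectors/frame. Both thresholds were
calibrated on the synthetic spatially-smooth, temporally-independent null,
where the best offset is essentially random and correlations collapse.
At radius-amplitude/noise = 3 the detector achieves TPR ≥ 0.9 and
FPR ≤ 0.1 over 50+50 seeded movies with median wave-speed error < 25%
(typically ~2%). The closed-boundary constraint quantizes the wavenumber,
so the generator reports the realized lateral speed alongside the request.

## Group comparison

Distributions are built per the study's conventions: time-averaged per-FA
values for intensity, area, sliding speed, lifetime and elongation;
per-frame values for number per cell. Groups are EGF bins (no = 0 nM,
low = 0.01/0.1, high = 1/10/100) or slow/fast at the 2-means cutoff
(strictly greater than = fast). Three-group differences are the arithmetic
mean of the three pairwise KS statistics. Families are fitted by
Nelder–Mead minimization of the one-sample KS distance over
log-transformed positive parameters from moment/quantile starts
(tolerance 1e-6); lognormal for the skewed positives, Weibull for sliding
speed, Gaussian for edge velocities.

**Mean tests.** Welch's t-test at p < 0.01 (the unequal-variance form is
the safer default when a "t-test" is unspecified; the pooled Student
variant is a config switch). Crucially, the test runs on statistically
independent units: per-FA values for FA characteristics, but per-cell
means for FA number per cell and for edge velocities, whose pooled
per-frame/per-entry samples are strongly autocorrelated within one cell —
pooling them into a t-test would be pseudo-replication and flags every
null dataset. The pooled samples still feed the KS summaries and fits,
matching the distribution-construction conventions above.

**Null calibration.** On condition bundles with identical generator
parameters at every dose (and the wave/fast-cell coupling disabled so every
comparison is null by construction), 19 of 20 seeded replicates at the
sizes used in `tests/test_acceptance.py` produce no significant flag at
all — 1 flag in 296 tests, below the nominal 1% per-test rate (the Welch
test is slightly conservative at these group sizes). The
averaged-pairwise-KS null envelope calibrated at those replicate sizes is
0.25–0.32 for the per-FA characteristics (0.45 for lifetime, whose
uncensored-track counts are smallest) and 0.55 for number per cell, whose
per-frame counts are autocorrelated within a cell and carry a small
effective sample. The envelope scales with the replicate sample sizes and
holds only for them.

## Condition datasets

`make_condition_dataset` generates per-dose trajectories (per-cell RMS
speeds lognormal with dose-dependent median and CoV), adhesion movies
(dose-scaled peak intensity and birth rate) and edge movies (waves riding
on fast cells unless decoupled). The default dose map imposes the
qualitative structure such experiments report: median speed rising then
saturating (25→32 µm/hr), speed CoV rising monotonically (0.20→0.60),
adhesion intensity falling monotonically (scale 1.0→0.42), and adhesion
number per cell peaking at low doses (birth rate 0.5→0.9→0.5). The full
pipeline recovers all three orderings and ranks intensity and
number-per-cell as the two largest averaged-pairwise-KS characteristics
under EGF binning at 40 cells and 2 movies per dose (the problem sizes
used by the end-to-end acceptance run; smaller sizes leave the CoV
ordering to sampling noise).

What the generator does **not** emulate: optical PSFs and evanescent-field
depth, cell shape change in adhesion movies, adhesion maturation-state
subpopulations, spatially structured adhesion placement, autocrine
signaling, or any mechanistic link between a cell's adhesions and its own
migration speed beyond the imposed dose- and speed-group structure.
Passing recovery tests therefore demonstrate that the analysis measures
what it claims on data obeying its assumptions — not that those
assumptions hold for any particular experiment.

## Numerical conventions

Pixel indices are 0-based, origin top-left, y down; physical coordinates
in µm via the pixel size; frame intervals in seconds for movies, sampling
intervals in minutes for tracks; intervals are half-open in frame indices.
Movies travel as multi-page grayscale TIFF with a JSON sidecar carrying
pixel size, frame interval and generator parameters — a missing
calibration is an error, never a silent default. Reports round floats to
10 digits and are byte-identical for identical configs and seeds; every
generator is a pure function of its parameter record including the seed.
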