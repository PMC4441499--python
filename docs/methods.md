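# Methods

This note records the modelling choices behind `erpmicro`: what each stage
assumes, the parameters that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Data model and preprocessing

All topographic analysis operates on average-referenced ERPs
(channels × samples, µV) over a half-open epoch window, by default
[−200, 700) ms at 500 Hz — exactly 450 samples; 0-based sample indexing
throughout.  Preprocessing follows standard evoked-potential practice:

- **Band-pass 1–30 Hz, notch 50 Hz.**  Second-order-sections Butterworth
  (one-pass order 2, applied forward–backward: effective order 4, zero
  phase) plus a 2 Hz-wide IIR notch.  Zero-phase filtering matters because
  latencies (microstate onsets, EMG onsets) are read off the filtered data.
- **Artifact rejection at 65 µV**, strict inequality, applied on the
  retained analysis channels only.  Trials are flagged, never silently
  dropped, so rejection counts are auditable.  A subject is discarded when
  any condition retains fewer than 40 artifact-free trials.
- **Channel repair** by Perrin-style spherical-spline interpolation
  (stiffness m = 4, 20 Legendre terms, diagonal regularization 1e−5).  The
  spline reproduces constants exactly and smooth low-order fields to a few
  percent, which is the regime bad-channel repair is used for.
- **Montage.**  Electrode positions live on the unit sphere.  The packaged
  layout is a Fibonacci-spiral quasi-uniform covering of the upper
  hemisphere (z ≥ −0.2), ordered from vertex downward; the 128-channel
  variant reduced by its 18-channel outermost belt gives the 110-channel
  analysis set.  A real geodesic-net geometry is proprietary; ordering the
  spiral by height makes "outer belt" a static index list and keeps every
  test geometry-free.

## Microstate segmentation

Clustering is **polarity-sensitive**: maps are compared by signed spatial
Pearson correlation, the evoked-potential convention (a polarity reversal
is a different component, unlike in spontaneous-EEG microstate work).
AAHC starts from singletons; the "worst" cluster is the one with the lowest
summed GEV contribution `Σ (GFP·r)²`; its members are reassigned to the
highest-correlating surviving cluster; centroids are the unit-normed mean
of the member maps (raw maps, so high-GFP samples weigh more).  All
tie-breaks go to the lowest index, making the procedure deterministic.

Model order: the Krzanowski–Lai statistic is computed with dispersion
`W(k)` = mean within-cluster dissimilarity (1 − r of samples to their
centroid), `DIFF(k) = W(k−1)(k−1)^{2/p} − W(k)k^{2/p}` with p the channel
count, `KL(k) = |DIFF(k)|/|DIFF(k+1)|`, restricted to k where the W curve
is locally convex; the argmax wins, ties to the smaller k.  The exact
"modified KL" used by the originating software is not published; this
variant is declared, not inferred.  If no k qualifies (featureless curve)
the fallback is the smallest k reaching GEV ≥ 0.9.

The 10-sample (20 ms at 500 Hz) minimum-duration rule is applied after
clustering, iteratively until stable: each sample of a short interior run
is relabeled to the better-correlating flanking template.  Runs touching
the epoch edges are exempt — the window truncates them, so their observed
duration is uninformative.

GEV is monotone in k only up to the greedy reassignment during
atomization; microscopic inversions (~1e−6) occur and are tolerated.

## Back-fitting and statistics

Back-fitting is per-sample argmax of signed spatial correlation against the
window's candidate templates only (the competitive design); no duration
constraint at this stage.  Zero-variance samples are labeled "unassigned"
and excluded from presence sums.  Presence is reported in ms (1000/fs per
sample).

The Condition × Map repeated-measures ANOVA uses the standard two-way
within-subject sums-of-squares decomposition (delegated to statsmodels'
AnovaRM) with **uncorrected** degrees of freedom — no sphericity
correction, matching how such designs are conventionally reported.  Planned
comparisons are one-way within-subject contrasts whose F(1, n−1) equals the
squared paired t; identical data give F = 0 (the 0/0 case is resolved to
"no effect").

Voxel-wise source statistics: paired t per solution point (df = n−1,
two-tailed; at n = 15 and α = .05 the critical t rounds to 2.14), positive
t meaning the first condition is stronger.  Zero-variance voxels are
excluded and logged.  Contiguity filtering removes suprathreshold connected
components smaller than 10 voxels, computed separately for positive and
negative voxels over **face (6-)connectivity** — the most conservative
standard notion of "contiguous"; raising the extent threshold can only
shrink the mask.

## Forward and inverse model

Head model: three concentric spheres (brain/skull/scalp radii 87/92/100 mm,
conductivities 0.33/0.0042/0.33 S·m⁻¹).  For each Legendre degree the
radial boundary-value problem (potential and radial-current continuity,
insulating outer boundary) is solved as a small linear system, so the same
code handles any shell profile; the series is truncated at 60 terms, ample
for sources kept inside 93% of the brain radius.  In the equal-conductivity
limit the solver reproduces the homogeneous-sphere closed form (derived
independently by generating-function summation) to < 1e−8 relative error.
Units: gain in µV per nA·m; source coordinates in model mm (no anatomical
atlas or template-brain registration — out of scope).

Solution points: a cubic lattice clipped to the brain sphere, spacing
bisected so the count lands within 10% of the request (full-scale 3001,
test-scale ~300).  Prior neighbors are lattice points within 1.5× spacing;
cluster statistics use the stricter face adjacency.

LAURA prior: for point i with neighbors k at distances d_ik, the prior
matrix has off-diagonal −d_ik⁻² (normalized by neighbor count) and diagonal
Σ d_ik⁻² — the local autoregressive structure that mimics the
inverse-square fall-off of physical potential fields.  The exponent is a
declared choice; the source literature gives no number.  Because L
annihilates locally constant fields, LᵀL is singular; a ridge of 0.2× its
mean diagonal stabilizes it.  The precision is additionally depth-weighted,
`P = D(LᵀL + ridge·I)D` with `D = diag((‖a_i‖/mean)^0.9)` (a_i the
three-column gain block of point i): without gain-norm compensation the
moment-norm peak of any minimum-norm-family estimate sits superficially
regardless of the true depth — depth weighting is the standard remedy.
With `prior="identity"` all weighting is bypassed and the kernel is exactly
Tikhonov minimum norm.  The default λ fixes the whitened SNR at 3
(λ = trace(A P⁻¹Aᵀ)/(C·SNR²)), configurable.

Current density is the Euclidean norm of the 3-component moment estimate.
For **localization validation** the package uses the variance-standardized
(sLORETA-style) score `√(m_iᵀ S_ii⁻¹ m_i)` with S the per-point estimate
covariance (`apply_inverse(..., standardize=True)`): the plain norm peak is
displaced by 20–45 mm at 110-channel resolution, while the standardized
peak localizes noiseless single dipoles essentially exactly (20/20 within
two grid spacings on the ~300-point grid, every seed tested).  Group
contrasts in the pipeline use the plain norm, keeping the dependent
variable a current density.

## EMG screening and onset

The rectified trace is summarized in nine 100 ms bins over [−200, 700) ms,
each the mean over a 300 ms window centred on the bin (truncated at the
edges).  The baseline threshold is mean + 2 SD of the rectified
pre-stimulus samples.  A trial screens "active" when some post-stimulus bin
exceeds the threshold **and** that bin's raw rectified samples differ from
baseline by a two-sample t-test (α = .01); with degenerate variance the
threshold rule alone decides.  On pure-noise trials the false-positive rate
is ≈ 0 (a bin averages ~150 samples, so exceeding baseline + 2 SD of raw
samples is very unlikely under H0).

Onset: the first crossing of the threshold by a **short (25 ms) centred
moving average** of the rectified trace, searched from the start of the
first suprathreshold bin, refined to ms by linear interpolation.  The
300 ms average is deliberately not used at sample level: a 300 ms centred
window lifts above a near-baseline threshold up to ~150 ms before the true
burst, an intrinsic early bias larger than the accuracy the measure is
meant to have; the short window keeps the mean recovery error under 10 ms
at SNR 10 (planted 415 ms onsets recovered 50/50 within ±50 ms).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* the pipeline consumes: hidden
per-condition label sequences over templates that are forward-projected
dipoles (so inverse recovery has a known answer), GFP shaped as half-sine
bumps per segment with a 30% floor (so segment-boundary samples keep a
defined topography), per-subject lognormal(0, 0.1) amplitude scales and
±10 ms latency jitter, and spatially white Gaussian sensor noise
re-referenced to the average.  SNR means peak signal GFP / noise GFP; the
recovery suites run at SNR 5 with 15 subjects.  Cued-CPT schedules follow
the 80/80/240 Go/NoGo/distractor design (200 ms stimuli, 1650–2000 ms ISI,
cue immediately before every target, no immediate letter repeats).

Not emulated: between-subject topographic variability (only amplitude and
latency vary — no published model exists for the former), correlated or
non-stationary noise, ocular artifacts, volume-conducted EMG, or overlap
between successive trials.  Passing recovery tests therefore demonstrates
the correctness of the algorithms under the stated generative model, not
their behaviour on real recordings.

## Problem sizes

Test and acceptance runs use the scales at which the methods are exercised
throughout this repository: ~300 solution points (the test-scale grid), 15
synthetic subjects per cohort, 10 cohorts for model-order selection, 20
random dipoles for localization, 2000 voxels / 500 trials for null
calibration, 50 trials for onset recovery.
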