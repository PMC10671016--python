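# Methods

## The measurement being modelled

An implantable needle-shaped CMOS image sensor (40 × 90 pixels at 7.5 µm
pitch, a 300 µm × 675 µm field, micro-LED excitation at the top and bottom
of the array) records dLight1.2 fluorescence in the nucleus accumbens (NAc)
at up to 10 frames/s. dLight emission tracks extracellular dopamine, so a
subcutaneous drug injection at t = 0 produces a session-wide fluorescence
transient whose shape reflects the drug's mechanism: opioids disinhibit
VTA dopamine neurons (slow rise, slow decline), dopamine-transporter
blockers prevent reuptake (fast rise, deep delayed undershoot), and a
saline control is flat.

The pipeline quantifies this as per-pixel ΔF/F₀ % = (F − F₀)/F₀ × 100 with
a per-pixel baseline F₀, detects regions of heightened activity by adaptive
binarization + morphology, and tests group time courses with a one-way
repeated-measures ANOVA. Since no public recordings are deposited, the
package ships a ground-truthed synthetic session generator and validates
every stage against what it plants.

## Synthetic session generator

A session is `I(x, t) = B(x) · bleach(t) · (1 + c(x) · k(t)) + noise`.

**Baseline `B(x)`** — 1000 sensor counts (DN) with a linear 10 % fall-off
across rows, emulating illumination heterogeneity from the edge-mounted
micro-LEDs. Units are arbitrary DN; ΔF/F₀ cancels the absolute scale (a
tested invariance).

**Kinetics `k(t)`** — zero for t ≤ 0; for t > 0 a Bateman
difference-of-exponentials normalised to unit peak, minus a logistic
undershoot step:

    k(t) = A · (e^(−t/τ_d) − e^(−t/τ_r)) / B_max  −  U / (1 + e^(−(t−t_u)/s_u))

The Bateman form is the standard absorption–elimination transient; its
closed-form peak is t* = τ_r τ_d/(τ_d − τ_r) · ln(τ_d/τ_r). Defaults:

| class | A | τ_r (min) | τ_d (min) | U | t_u (min) | s_u (min) | t* |
|---|---|---|---|---|---|---|---|
| morphine-like | 0.10 | 18 | 90 | 0.015 | 150 | 20 | 36.2 |
| cocaine-like | 0.12 | 8 | 50 | 0.04 | 130 | 8 | 17.5 |
| saline | 0 | – | – | 0 | – | – | – |

These were chosen so the 15-min-binned peak falls inside the reported
windows (morphine 30–60 min, cocaine 15–45 min) and so the cocaine-like
curve rises faster and ends in a sharp sustained sub-baseline plateau near
130–150 min. An injection-handling artifact subtracts 0.03 (ΔF/F₀
fraction) inside a 4-min rectangular window straddling t = 0 — the one
intentional discontinuity of the curve — so the dip appears in the 0–5-min
binned image.

**Spatial coupling `c(x)`** — 12 Gaussian release sites (σ ∈ 1.5–3 px,
per-site gain ∈ 0.7–1.3) placed uniformly at random with a 12 px minimum
separation and a 4 px edge margin, plus a uniform background coupling of
0.3 seen by every pixel. The separation/margin keep planted sites
*resolvable as distinct ROIs* — the detection pipeline deliberately does
not watershed-split touching components, and a site truncated by the sensor
edge has no well-defined centroid to recover. Between-seed variation in the
realised coupling map is what plays the role of between-animal variability
in the group statistics.

**Noise** — Gaussian read noise (SD 5 DN) plus a variance-proportional
shot-like term (variance 0.5 DN per DN of signal, i.e. a conversion gain of
~0.5 DN/e⁻), giving ≈ 2.3 % per-pixel per-frame ΔF/F₀ noise at baseline.
No fixed-pattern noise, motion, or optics/PSF modelling. Optional
mono-exponential photobleaching exists but is off by default, and no
detrending is applied downstream (none is part of the analysis being
reproduced).

**Timing** — sessions default to 15 min pre- and 225 min post-injection
(the analysis span) at 0.2 frames/s (one frame per 5 s). The hardware rate
of 10 FPS is supported but a full-rate 4-h session is ~144k frames; all
downstream operations are rate-agnostic (occupancy is a fraction, bins are
time-based), so the desk-scale rate changes nothing but noise averaging.
A duration of D minutes at rate r yields floor(D·60·r) frames with
timestamps at frame centres.

## ΔF/F₀ processing

* F₀ is the per-pixel temporal mean over the 15 min immediately preceding
  the injection (window [−15, 0) min), not the full 2-h acclimation; the
  choice is exposed as configuration. A scalar whole-image F₀ is available
  as an option, but per-pixel is the default ("each pixel normalised to its
  baseline").
* Pixels with F₀ ≤ 0 after background subtraction are excluded (flagged
  invalid and NaN downstream) rather than clipped, since dividing by ~0
  makes ΔF/F₀ unbounded.
* Interval averaging tiles time as ((k−1)·w, k·w], anchored at the
  injection and mirrored pre-injection, labelled by the interval *end*
  time: "the 30-min mark" is the mean over (15, 30]. A trailing interval
  not fully covered by the recording is dropped. The (−15, 0] bin is the
  pre-injection control bin.
* Known consequence of the above: the handling artifact straddles t = 0, so
  ~2 min of the baseline window are depressed by the dip. This biases F₀
  low by ~0.4 % of the coupling, i.e. all post-injection bins inherit a
  small constant positive offset (~0.1–0.2 %). Peak locations and the drug
  contrasts are unaffected, but with the near-noiseless whole-image means
  the offset is statistically detectable: a *default* saline group shows a
  significant pre-vs-post difference. The generator's saline control is
  flat in its kinetics (amplitude 0); statements about test size under the
  null therefore refer to the artifact-free null (`artifact_depth = 0`),
  which is what the type-I-error simulation uses.

## ROI detection

Per post-injection frame: a pixel is active iff its ΔF/F₀ exceeds the local
mean over an 11 × 11 replicate-padded neighbourhood by 1.0 (percent units;
invalid pixels are excluded from the mean via normalised convolution and
are never active). Each binary frame is cleaned by morphological opening
then closing with radius-1 disk (diamond) elements — the open–close filter
is idempotent, which the tests assert. The per-pixel occupancy (fraction of
analysed frames active) is thresholded at 0.05, 8-connected components are
extracted, and components outside 6 px – quarter-frame are discarded. ROIs
are numbered 1..n in raster order of their centroids; the heatmap appends a
whole-image row "W". Detection on 5-min averaged images instead of raw
frames is supported (`average_width`), raw frames are the default.

Border conventions (outside counts as inactive for opening and for the
closing dilation, active for the closing erosion) and the earliest-interval
tie-break in peak detection are fixed choices where the analysis had to
pick something; both are documented in the docstrings and exercised by the
from-definition oracle tests.

## Group statistics

Each animal contributes one complete row of 15-min interval means
(pre-control bin plus 15 post-injection bins by default). The omnibus test
is the standard subject × time partition computed from first principles:
SS_total = SS_subject + SS_time + SS_error, F = MS_time/MS_error with
df = (k−1), (n−1)(k−1). No sphericity correction is applied by default —
with n = 3 animals and k = 16 labels the Greenhouse–Geisser estimate is
unstable; this is a documented limitation. Zero error variance is flagged
(`degenerate_variance`) and the p-value reported as a machine-epsilon
bound.

Post-hoc comparisons test each post-injection label against the pre
control, Holm-adjusted. The default uses the pooled ANOVA error term
(MS_error at df_error) — a protected vs-control comparison. The rationale:
the dominant between-animal variability in these sessions is a shared
multiplicative gain, under which every label's plain paired t collapses to
the same statistic with only n−1 = 2 degrees of freedom, leaving the
procedure with essentially no resolution after a 15-fold Holm correction
regardless of effect size; pooling borrows the interaction degrees of
freedom, as is standard for protected comparisons-vs-control, at the price
of assuming homogeneous error variance across labels. The classic per-pair
paired t (`posthoc="paired"`) and unadjusted/Bonferroni alternatives remain
available as configuration. Group figures plot mean ± SD (SEM is also
computed and reported).

## Problem sizes and numerical choices

* Default sessions: 2880 frames of 40 × 90 float64 (~83 MB in memory,
  float32 on disk); a three-animal group runs in ~5 s per drug plus ~1.5 s
  per session for ROI detection.
* The type-I-error simulation (200 null triplets) runs the real generator →
  ΔF/F₀ → binning → ANOVA path on a reduced 10 × 18 sensor at 0.05
  frames/s; the F statistic's null distribution does not depend on sensor
  size, and this keeps 600 sessions inside a test suite run.
* Planted-site recovery is scored over 20 default-condition sessions by
  nearest-centroid matching with a 2 px tolerance.
* Interval assignment nudges t/w by 1e−9 so frame times landing exactly on
  a bin boundary go to the earlier bin deterministically; simulated frame
  centres never land on boundaries.
* All randomness flows from a single integer seed per session through
  `numpy.random.default_rng`; identical parameters give bit-identical
  stacks, and a full pipeline rerun is byte-identical (hashed manifests).

## What passing tests do and do not show

The generator reproduces the *trends* the analysis is meant to resolve —
peak windows, rise-speed ordering, undershoot ordering, control flatness —
with realistic sensor noise, illumination heterogeneity and a handling
artifact. It does not model motion, hemodynamics, fixed-pattern noise,
bleaching-by-default, or the unknown true spatial statistics of NAc release
sites. Recovery of planted truth therefore validates the implementation of
the analysis, not the biology: on real recordings the absolute ΔF/F₀
magnitudes, ROI counts and significance patterns will differ.
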