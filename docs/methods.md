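# Methods

## The detection pipeline

`fallwin` treats fall detection as binary classification of short windows
of tri-axial acceleration. All signals are in g (1 g ≈ 9.81 m/s²),
gravity-inclusive, uniformly sampled; sample *i* of a trace lives at
*t = i / rate* with *t = 0* at the first sample, and sample intervals are
half-open and 0-based throughout.

**Windowing.** An event window of *n* seconds is split into *m*
sub-windows with pairwise overlap fraction *o*; the sub-window length is
*L = n / (m − (m−1)o)* seconds (for *m = 1*, *L = n* regardless of *o*).
Sub-window length and hop are rounded to whole samples and the last
sub-window is anchored to end exactly at *n·rate*, so rounding error
cannot accumulate. The default scheme (3 s, 2 sub-windows, 50 % overlap)
yields sub-windows [0, 100) and [50, 150) samples at 50 Hz. A trace one
sample longer than the window (151 samples for a 3 s event at 50 Hz, an
off-by-one some archives exhibit) is truncated; any other length mismatch
is an error, because padding would fabricate data.

**Features.** Per sub-window and axis: mean, median, population standard
deviation, skewness m₃/σ³ and non-excess kurtosis m₄/σ⁴ (population 1/n
moments, no bias correction — the literal definitions), maximum and
minimum; plus one 3-axis slope √(Σ_axis (max−min)²). A constant sub-window
has σ = 0, where skewness and kurtosis are 0/0; both are reported as 0,
a convention chosen so shift-invariance holds degenerately. Feature names
follow the pattern `m_`/`me_`/`sd_`/`sk_`/`k_`/`max_`/`min_` + axis +
1-based sub-window index, and `SLOP<s>`; ordering is feature-major within
each sub-window, sub-windows concatenated in time order. Any fixed order
is equivalent for the classifiers, but files produced by this package are
only interchangeable with implementations that use the same documented
order.

**Detectors.** Features are z-scored with statistics fitted on training
rows only (zero-variance features get unit scale). Standardization is ON
by default: mean-g features and kurtosis differ by orders of magnitude and
nearest-neighbor distances are scale-sensitive; a flag restores the raw
scale. The k-NN detector (default k = 1) uses Euclidean distance computed
directly against the standardized training matrix, with distance and vote
ties resolved to the smallest training index — a deterministic contract a
generic library classifier does not guarantee. The SVM is a C-SVC with RBF
kernel, C = 1, and γ = 1/(n_features · Var X) computed on its training
input. Model archives are single joblib files with a format version.

**Class balance.** SMOTE is applied to training folds only: each synthetic
minority row is *p + λ(q − p)* with *p* a uniformly drawn minority row,
*q* one of its k = 5 nearest minority neighbors (Euclidean; k clamps with
a warning when the minority is small), λ ~ U[0, 1]. Every class is raised
to the majority count; originals are preserved first and synthetic rows
carry a sentinel subject id, which the fold audit uses to prove none ever
reaches a test fold.

**Evaluation.** Metrics come from TP/TN/FP/FN with falls positive:
accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision,
F1, and macro-average accuracy (the unweighted mean of per-class
accuracies; for binary labels exactly (sensitivity+specificity)/2). A
zero-denominator ratio is reported as 0 and flagged rather than raising,
so parameter sweeps survive empty-positive folds. k-fold splits shuffled
rows as evenly as possible; 30-fold is plain k-fold with k = 30 (random
rows, not subjects); LOSO makes one fold per subject. Fold plans are
audited: test folds must partition the rows, LOSO folds must be
subject-disjoint.

**Streaming.** Over a continuous recording, windows of W seconds slide
with hop H = W(1 − o); the decision for window *t* is available at
*tH + W* and may only use samples up to the window end (asserted at run
time). A FALL decision stamps an alarm at the window end. Scoring is
event-level for sensitivity — an annotated fall counts as detected iff at
least one alarm window overlaps the interval padded by ±3 s (one window
length; configurable) — and window-level for specificity, over windows
that do not overlap any padded fall interval. Windows that overlap a fall
but raise no alarm are ambiguous and excluded from specificity. Rate
harmonization for mixed-rate recordings uses plain sample-dropping
decimation for integer ratios and piecewise-linear interpolation otherwise
(both exposed; linear is the default since e.g. 87→50 Hz has no integer
ratio).

**Attribution.** Shapley values are estimated by permutation sampling with
background imputation: for a sampled feature permutation and background
row, features are switched from the background's values to the instance's
in permutation order, and each feature is credited the score increment it
causes. The explained score is the positive-class vote fraction (k-NN) or
the signed decision value (SVM). The estimator is model-agnostic, exact
under full enumeration (≤ 8 features), satisfies the null-player property
exactly, and reports per-feature Monte-Carlo standard errors plus the
standard error of the attribution total, against which the efficiency
identity Σφ = f(x) − base is checked. The default background is a seeded
100-row subsample of the training set. Dependence "plots" are emitted as
tidy tables; rendering is left to the user.

## The synthetic generator

The generator emulates the two study settings: single-event 3 s windows
at 50 Hz within ±2 g, and long continuous recordings (e.g. 1200 s) with
annotated falls, heterogeneous rates (20/50/100 Hz) and ranges available
through the config.

A fall is: quiet 1 g baseline on a random orientation → a balance-loss
oscillation (~0.5 g, 3–6 Hz) whose amplitude grows toward the impact,
lasting at most ~1.2 s however long the fall → a 0.08 s free-fall dip in
which the resultant magnitude ramps toward ~0 g → a damped impact burst
(default 1.5 g nominal amplitude, drawn ×[1.15, 1.4], 9 Hz ring-down over
0.45 s, saturating toward the ±2 g range) at a new "lying" orientation →
a smaller settling bounce → rest. The fall duration is uniform on
[1, 3] s and the impact lands in the second half of the window, as in
single-event archives where windows are centered on the event. ADL
subtypes: walking (~2 Hz gait with a weak first harmonic), sitting down
(a single 0.8 g-scale spike plus a small posture shift — the designed
hard negative between ADL baseline and fall impact), jumping (repeated
spikes), lying still (gravity + noise), and slow posture transitions.
Sensor noise is additive Gaussian (default 0.03 g per axis). Per-subject
effects are a multiplicative amplitude jitter (1 + N(0, 0.1) by default)
and a small per-axis offset (N(0, sd/10), the scale of a real
accelerometer bias), giving LOSO a genuine domain gap. Continuous
recordings stitch 3 s ADL blocks with one gravity orientation threaded
through and oscillatory components tapered at block edges, so block seams
are not impact-like artifacts; falls replace randomly chosen blocks and
are annotated with their true interval, through impact and bounce.

Everything regenerates bit-identically from a seed: per-event generators
are keyed by (seed, subject), per-subject effects by the config seed, so
a subject's "style" is stable across their events.

What the generator does **not** emulate: biomechanically realistic limb
dynamics, device-specific noise spectra and drift, gyroscope channels,
real inter-class confusion structure (e.g. syncope-like slow falls), or
realistic activity transition statistics. Passing tests on synthetic data
therefore demonstrate the *pipeline's* correctness — segmentation,
features, balancing, protocols, attribution — and the qualitative
separability structure the feature bank targets, not field performance on
real falls.

## Numerical and design choices

- Decimation drops samples without an anti-alias filter — the simplest
  faithful reading of "down-sampling"; the linear path is available when
  aliasing matters.
- Trailing partial windows are dropped, never padded.
- SMOTE duplicate degeneracy (nearest neighbor at distance 0) yields a
  synthetic point equal to its parent; allowed.
- Event/specificity match tolerance defaults to 3 s (one window) and is
  configurable; the choice of how to partition windows near a fall for
  specificity is not canonical, so it is documented rather than hidden.
- CLI configs are JSON; every output embeds the config hash and seed.
  Exit codes: 0 ok, 1 data error, 2 usage error.
- Sub-second parameters of the fall morphology (dip 0.08 s, ring-down
  0.45 s, transient cap 1.2 s) were fixed once so that the documented
  amplitude ordering between the onset and impact halves of a fall window
  holds for essentially all draws; the signal is gravity-dominated, so
  the ordering is a small margin on top of a ~0.58 g RMS floor.

## Problem sizes used by the test suite and acceptance script

Unit tests run on small configurations (3–4 subjects, tens of events).
The acceptance script and end-to-end tests use the full stated study
conditions: 10 subjects with 200 falls / 800 ADLs for cross-validated
detection, one 1200 s recording for the streaming protocol (571 windows
at 30 % overlap), six 600 s recordings pooled for trained-detector
streaming at 50 % overlap, 1000 random windows for the feature-bank
oracle comparison, and 150 permutations per Shapley attribution. The
trained-detector streaming numbers are reported at 50 % overlap because
with a 1.5 s hop every impact is well-placed in at least one window; at
sparser hops the single-event-trained detector can miss impacts that land
early in every window — the alignment effect that motivates sweeping the
streaming overlap in the first place.

## Known limitations

- The 1-NN detector stores its full standardized training matrix; memory
  and prediction cost grow linearly with training size.
- Shapley enumeration is capped at 8 features; beyond that only the
  sampling estimator is available.
- Multi-class use (ADL subtypes) is supported by the metrics and the SVM
  (one-vs-one internally), but the pipeline's defaults binarize to
  FALL/ADL.
- The generator's amplitude distributions are order-of-magnitude choices
  constrained only loosely by published fall-trace morphology; absolute
  performance numbers on synthetic data should not be read as field
  performance.
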