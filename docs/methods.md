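# Methods

## Problem and data model

The package classifies the behaviour of a freely moving dog from a
harness-mounted inertial logger placed dorsally between the scapulae.  The
logger provides six channels at 100 Hz in a body-fixed coordinate system
(x toward the head, y to the right, z into the body): acceleration a_x,
a_y, a_z in g and angular velocity ω_roll, ω_pitch, ω_yaw in °/s about the
same axes.  Ground truth comes from video annotation stored as SubRip
(SRT) subtitle tracks; each cue names one of seven mutually exclusive
categories (lay, sit, stand, walk, trot, canter, gallop).  Intervals are
half-open `[start, end)` seconds on the recording clock; recordings and
tracks are assumed pre-aligned (the simulator emits them aligned, and
video/sensor synchronization is outside this package's scope).

Because annotation is least reliable near behaviour transitions, a margin
(default 1 s) is removed from both ends of every labelled interval before
any window is cut; intervals of ≤ 2 × margin vanish.  The operation
deliberately is not idempotent — applying it twice trims twice — and a
test pins the trim to exactly 2 × margin per surviving interval.

## Features

Derived per-sample signals: |a| and |ω| (vector norms), angular
acceleration α (per-axis finite differences of ω — central differences in
the interior, one-sided at the ends, in °/s²), the attitude tangent
r = a_x / a_z (with |a_z| clamped to ε = 0.05 g, keeping its sign, so the
ratio cannot blow up in dynamic windows; ε is far below the ≈1 g posture
values the ratio is meant to capture), the dot product d = a·ω and the
cosine alignment c = d/(|a||ω|) (defined 0 where either norm vanishes,
clipped to [−1, 1]).

Each labelled one-second window (100 samples; windows advance by a stride
of 10 samples by default and must lie entirely inside a single labelled
interval, with interval endpoints floored to the sample grid) yields nine
statistics per scalar signal: mean, standard deviation (population),
skewness, excess kurtosis, min, max, mean-crossing count, dominant FFT
frequency and dominant FFT magnitude.  Conventions chosen where the
definitions are genuinely open:

* skewness and kurtosis of a zero-variance window are 0 (not NaN);
* the mean-crossing count is the number of strict sign changes of the
  mean-centred signal between consecutive samples;
* the FFT is the plain rectangular-window transform; magnitudes are
  amplitude-scaled (2|X_k|/n) so a pure sinusoid of amplitude A scores ≈ A,
  and only bins 1..n/2 compete for the dominant bin;
* the six extra |ω| features are the spectral magnitudes at multiples
  2..7 of its dominant bin (0 beyond the Nyquist bin), summarizing the
  harmonic structure of the gait.

The manifest — name, source signal, statistic, sensor group per feature —
is data-driven (CSV-loadable) and validated at import: 126 features total,
45 accelerometer-only (9 × {a_x, a_y, a_z, |a|, r}), 69 gyroscope-only
(9 × {ω_roll, ω_pitch, ω_yaw, |ω|, α_roll, α_pitch, α_yaw} + 6 harmonics),
12 mixed (9 × d + mean/min/max of c).  The exact published feature table
is not available, so this manifest is an explicit reconstruction honoring
all printed counts; a future exact table can be dropped in via the CSV
without code changes.

Features are min-max normalized to [0, 1].  Parameters are always learned
on training data only (inside each cross-validation fold, on that fold's
training split); constant columns map to 0 and out-of-range validation
values clip to [0, 1].

## Classifier

A soft-margin SVM with Gaussian kernel K(u, v) = exp(−γ‖u−v‖²), defaults
C = 16, γ = 0.001.  Multiclass handling is one-vs-one voting (the libsvm
default, and what `sklearn.svm.SVC` implements).  A grid scan over
C ∈ 2^{−5,−3,…,15}, γ ∈ 2^{−15,−13,…,3} with stratified, seeded five-fold
cross-validation reproduces the hyperparameter choice; folds are fixed
across grid cells so cells are directly comparable.  Sensor-subset masks
(accelerometer-only 45 columns, gyroscope-only 69; mixed features belong
to neither) are applied before the normalizer is fitted, so a masked model
never reads excluded columns.

## Validation framework

*Validation* always means prediction on measurements wholly excluded from
training — never pooled cross-validation folds — and the hold-out rule is
enforced structurally: any (dog, session) key on both sides raises before
computation.  Six schemes:

| scheme | training | validation |
|---|---|---|
| within_dog | one measurement of a dog | the dog's other measurement |
| intra_breed | one dog's best measurement | another dog of the same breed |
| inter_breed | one dog's best measurement | a dog of the other breed |
| multi_k_k (k = 1, 3, 5) | k + k measurements pooled over both breeds | a fixed pool of dogs absent from all training sets |

Measurements are ranked by *comprehensiveness* — the minimum window count
over the seven categories (0 if any is missing) — since freely moving dogs
perform the scripted behaviours in unequal amounts; each dog's more
comprehensive session is preferred, ties broken by total windows then
session index, and dogs rank by that score (ties: total windows, then id).
The top ten dogs per breed form the candidate pool.  Pairings within the
pool are seeded permutations (a cyclic derangement for intra-breed); the
multi-training schemes split each breed's pool into a validation half (up
to 5 dogs) and a training pool from which k measurements per breed are
drawn per calculation.  How the original study paired dogs is not
documented at this level of detail, so seeded random pairing without
replacement is this package's choice.  Each scheme runs N = 10
calculations by default.

Outcomes per window are graded by activity level A (lay = sit = stand = 0,
walk = 1, trot = 2, canter = gallop = 3): perfect match (exact category),
imperfect match (wrong category, ΔA = 0), and mismatches ΔA = 1, 2, 3.
The five percentages sum to 100 by construction.  Recognition matrices are
7 × 7 row-normalized percentages (rows = true category, columns =
predicted); rows with no true windows are undefined (NaN, exported blank),
never zeros.  Scheme matrices are entry-wise averages of the
per-calculation row-normalized matrices, re-normalized per row over the
calculations that define it.

Intercoder agreement compares two coders' (margin-trimmed) label tracks on
a shared node grid (default 0.1 s): nodes labelled by exactly one coder
count toward that coder's exclusive percentage (relative to that coder's
own node count); commonly labelled nodes give the agreement rate and a
row-normalized 7 × 7 matrix.

Feature importance uses the multiclass F-score
F(i) = Σ_c (x̄_i,c − x̄_i)² / Σ_c s²_i,c (unbiased class variances, classes
need ≥ 2 windows), which reduces to the classical two-class feature-ranking
F-score for two categories.  The score is invariant under common affine
rescaling of a feature and says nothing about redundancy between features.

## The simulator

`simulate` generates what the pipeline assumes about real data, not
biomechanically faithful dog gait:

* **Static postures** read the 1 g gravity vector rotated by a
  posture-specific attitude (lay: pitch 0°, roll 10°; sit: pitch 35°;
  stand: pitch 5°) plus Gaussian noise (0.02 g, 2 °/s); the gyroscope sees
  only noise, so postures are invisible to angular-velocity channels by
  construction — which is exactly why accelerometer-only models beat
  gyroscope-only ones.  Optional panting adds a small oscillation.
* **Gaits** superimpose a 3-partial harmonic series (amplitude ∝ 1/h,
  random phases per segment) of a stride frequency on every channel over a
  gravity baseline: walk 1.5 Hz, trot 3.0 Hz, canter 3.8 Hz, gallop
  4.2 Hz, with per-axis amplitudes rising with activity level (walk
  0.25–0.30 g / 15–25 °/s up to gallop 0.45–1.0 g / 62–100 °/s) and noise
  0.05–0.06 g / 5–6 °/s.  Canter and gallop get wide per-segment lognormal
  jitter (sd 0.09 on frequency, 0.15 on amplitude) so their distributions
  overlap heavily — the deliberate hard pair — while the gaps *between*
  activity levels are wide enough to survive both jitter and individual
  variation, keeping misclassifications concentrated within levels.
* **Individuals and breeds.** Each dog carries persistent lognormal
  frequency and amplitude factors (log-sd σ_ind, default 0.15) and a
  normal attitude offset (sd 30·σ_ind degrees); the two breeds shift
  template means in opposite directions (±6% frequency, ±8–10% amplitude,
  ±2° pitch).  σ_ind = 0.15 makes within-dog validation clearly outperform
  between-dog validation, the central finding this simulator must realize;
  σ_ind = 0 makes same-breed dogs identical and the gap vanishes (used as
  a control).  A study generates two sessions per dog from independent
  child seeds of one master seed, so sessions share the profile but not
  the noise.
* **Annotation structure.**  Behaviours are separated by 2 s unlabelled
  transition gaps (messier stand-like motion), emulating interrupted
  annotation; label intervals exactly tile the behaviour segments.  A
  simulated secondary coder jitters interval boundaries (sd 0.3 s) and
  relabels a uniformly drawn trailing fraction of confusable intervals
  (canter↔gallop up to 25%, stand↔lay up to 12%), yielding ~95–99%
  agreement concentrated on the same hard pairs.

What the simulator does **not** emulate: realistic gait waveforms (double
support, asymmetric strides), gravity/body-acceleration coupling during
turns, temperature drift, sensor saturation, panting by default, or any
GPS information.  Tests passing on this synthetic population therefore
show that the pipeline recovers structure *of the kind the method relies
on*; they do not certify accuracy numbers on real dogs.

### The separable control population

`separable_templates()` is a known-answer input: zero noise, zero jitter,
single-harmonic gaits at well-separated frequencies (2/4/6/9 Hz), a
distinct gallop amplitude scale, and **phase-locked** harmonics.  The
phase lock matters: the envelope of |ω| (and of a·ω) depends on the
relative phases of the three axis oscillations, which are redrawn per
segment, so even noiseless multi-phase data differs between sessions of
the same dog.  With phases locked and frequencies on exact FFT bins (no
spectral leakage) the two sessions are feature-identical by design, and a
correct pipeline must produce a 100%-perfect breakdown and an identity
recognition matrix — exercising the activity-level arithmetic and row
normalization against a known answer.

## Problem sizes and numerical notes

The test suite and the acceptance script run scaled-down studies chosen as
this package's own defaults for desk-scale verification: compact session
scripts (6–12 s per behaviour instead of the ~10-minute field protocol),
window strides of 20–25 samples instead of 10, and 2–10 dogs per breed in
replicate experiments; the acceptance script runs the full 24-dog, 48-
measurement design once at 12 s per behaviour (~15 000 windows).
Qualitative orderings are asserted as means over seeded replicate
populations (10 replicates; 30 for the saturating 3+3 → 5+5 multiple-
training step, whose effect size is a fraction of a percentage point).

All randomness flows through explicit integer seeds (numpy Generator /
SeedSequence); there is no hidden global RNG state, and every stage —
simulation, featurization, training, grid scan, scheme execution — is
bit-reproducible under a fixed seed.  Window statistics are validated
against naive two-pass moment oracles and a direct O(n²) DFT to 1e-9, and
windowing against brute-force end-sample enumeration.

## Known limitations

* The feature manifest is a reconstruction constrained by the published
  counts (126 = 69 + 45 + 12), not the original table; absolute accuracies
  depend on it even though the pipeline's orderings do not.
* Heavily overlapping windows (stride ≪ window) share samples; pooled
  cross-validation on such windows is optimistic.  Hold-out schemes are
  unaffected; the static-posture chance-level test uses non-overlapping
  windows for this reason.
* `a_x/a_z` is the only attitude tangent implemented; whether a second
  (a_y/a_z) tangent belongs in the feature set is an open question left
  configurable via the manifest.
* No attitude estimation or gravity/body-acceleration decoupling is
  performed; these are explicitly out of scope.
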