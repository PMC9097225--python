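# Methods

## Model

An epoch of wearable accelerometry is classified by which of two
multivariate references it sits closer to in Mahalanobis distance. Each
reference is the mean vector μ and population variance–covariance matrix
Σ of labelled per-second feature rows: one for seizure signal (the
tonic–clonic phase), one for daily activities. The features per second
are the mean and coefficient of variation of the three axes and of the
resultant force — eight numbers that capture both posture (axis means
encode the gravity projection) and movement intensity/irregularity (the
CVs). The decision needs no threshold: an epoch is a seizure call exactly
when its distance to the seizure reference is strictly the shorter one.

Assumptions worth stating: the sensor is rigidly mounted in a known
orientation (a rotated sensor changes axis means and CVs, which is
precisely the observed false-positive mechanism — see
`apply_displacement`); the sampling rate is uniform (irregular
timestamps are an error, never resampled); and both classes are
adequately summarised by a single mean and covariance, i.e. a
unimodal-cloud approximation of what is really a mixture of movement
classes. That last approximation is the method's main modelling
compromise and is inherited by this implementation.

## Parameters

| parameter | default | meaning |
|---|---|---|
| epoch length | 9 s | classification window; 3 and 6 s supported for the latency/false-alarm trade-off study |
| stride | 1 s | window shift |
| CV mean floor | 0.05 g | denominator of CV is max(\|μ\|, floor); keeps CVs bounded when an axis mean crosses zero |
| σ, Σ convention | population (÷n) | fixed for reproducibility; immaterial to the decision ordering at n = 50 samples/bin |
| minimum reference rows | 9 | 8-dim covariance needs ≥ 9 observations to be invertible |
| ridge | 1e-6 × trace/8 | added only when the smallest eigenvalue ≤ 1e-8 × trace/8; absolute floor 1e-12 for the all-constant degenerate case |
| aggregator | mean | per-second scaled distances √(D²/8) combined over the epoch; median/max available |
| refractory | 60 s | one alert per seizure |
| min consecutive positives | 1 | a single positive epoch alerts; raise to debounce short epochs |
| event-match tolerance | 5 s | a detection up to 5 s before the labelled onset still counts as that seizure |

The epoch-to-reference distance needed a design choice because a 9×8
epoch cannot be compared to an 8-dim reference directly. Three options
were considered: flatten the epoch to 72 dimensions (needs far more
reference data than 9 rows per movement can supply), take the distance
of the epoch's mean row (discards within-epoch variability), or
aggregate per-second distances. The last was chosen, with the
Mahalanobis–Taguchi √(D²/k) scaling so that reference members score
near 1 and typical epoch distances land in the low single digits. The
decision rule only uses the ordering of the two distances, so any
monotone rescaling applied to both sides leaves every decision intact.

Ties classify as non-seizure: for a monitoring alarm, specificity is the
scarce resource.

A second genuinely open point is whether reference rows are per-second
feature vectors or whole-epoch objects. Per-second rows are used: nine
rows per 9-s movement block is exactly the stated minimum for an
invertible 8-feature covariance, which is the reading on which the
arithmetic is self-consistent.

## Streaming semantics

The streaming detector keeps a rolling window of the last L feature
rows, classifies whenever a stride-aligned window completes, and fires
on the rising edge of a run of positive epochs: when the run reaches
`min_consecutive_positives`, the event fires unless the run began within
the refractory window of the previous event, in which case the whole run
is suppressed (one decision point per run; a long seizure never fires
twice). Streaming and batch classification are bit-identical by
construction, and `replay_equivalence` asserts it per recording.

## The simulator

Each movement segment is, per axis, offset + single sinusoid (random
phase) + Gaussian noise. Gravity contributes +1 g on Z for upright
postures and moves onto Y when lying on the side. The 15 daily-activity
classes use gait-plausible frequencies (walking 1.8 Hz, running 3 Hz,
body-shake 5 Hz) and amplitudes of 0–1 g; the seizure model is a rigid
tonic phase (sustained postural offset with a small 8-Hz tremor)
followed by a clonic phase of 3-Hz, 1.8-g oscillation on all axes, which
keeps the clonic axis CVs well above (≥ 1.5×) every daily class and the
class means ≥ 6 pooled standard deviations apart in at least one feature
dimension — both asserted in the test suite. The displacement artifact
rotates the sensor frame from a chosen onset; rotations preserve the
resultant force exactly, a cross-module invariant the tests exploit.

What the simulator does **not** reproduce: real canine biomechanics
(no gait harmonics, no amplitude drift, no transitions blending), real
seizure spectral content (no published quantitative characterisation
exists to emulate), sensor artifacts other than displacement, and
between-dog variability. Consequently, passing tests demonstrate that
the algorithmic machinery is correct and self-consistent — not that the
detector would achieve the same sensitivity/specificity on recorded
dogs. Synthetic class separations are generous by construction.

## Problem sizes and numerics

The test suite and the acceptance script run the pipeline on simulated
recordings of 300–1,800 s (plus a pure-arithmetic 40,545-row windowing
check), sizes chosen to exercise every code path with comfortable
margins while keeping the suite fast. Distances are computed through a
cached Cholesky factorization (never an explicit inverse); tiny negative
quadratic forms from round-off are clamped to zero. Covariance
regularization only activates on (near-)singular input, so
well-conditioned references are used exactly as estimated.

## Known limitations

- Two classes only; the multi-reference generalisation (one reference
  per movement) is out of scope.
- No probabilistic calibration of distances and no ROC analysis — the
  decision rule is threshold-free, though the reported distances would
  support one as an extension.
- References are global, not per-dog; individualised references would
  need the same pipeline with per-dog row selection.
- The CV floor (0.05 g) is an explicit artifact choice; raw CV with a
  near-zero mean is undefined and any floor value reweights low-motion
  features. Its value is configurable and logged.
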