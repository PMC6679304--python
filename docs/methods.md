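# Methods

This note documents the models, parameter choices, and numerical
conventions behind `emgrt`, and what the synthetic benchmark does and does
not demonstrate.

## Signal model of the synthetic generator

Each repetition emulates one relax–gesture–relax recording from an
8-channel, 200 Hz, 8-bit armband.  The signal is

    x[n, ch] = b[n, ch] + e[n] · g[ch] · σ_burst · w[n, ch]

where `b` is i.i.d. Gaussian baseline noise (σ_base = 2 raw units), `w` is
i.i.d. unit Gaussian carrier noise, `σ_burst` = 35 raw units, `g` is the
gesture's per-channel gain profile, and `e[n]` is a raised-cosine envelope
(0.08 s rise/fall) supported on the burst interval.  Samples are rounded
half-away-from-zero and clipped to the signed 8-bit range.  The burst
support defines the ground-truth onset/offset, independent of any
detector, which gives latency measurements an unambiguous reference.

Parameter rationale:

- **Burst duration 0.7 s ± 20 % jitter.**  Natural, briskly performed hand
  gestures last on the order of half a second to a second; the jitter
  prevents the classifier from keying on duration.
- **Relax head U(0.10, 0.35) s.**  Subjects in the emulated protocol begin
  relaxed and perform the gesture promptly after recording starts — a
  2-second training recording must fit the entire relax–gesture–relax
  sequence, which bounds the head at a few hundred milliseconds.
- **Gain profiles: one-hot dominant.**  Gesture *k* drives channel *k−1*
  at gain 1.0 and all others at 0.1.  Real gestures activate overlapping
  muscle groups; one-hot profiles are the cleanest separable geometry and
  are configurable (any rows in [0,1] that differ pairwise are accepted).
- **Amplitudes.**  σ_burst = 35 puts the burst at ~27 % of full scale with
  occasional clipping at the envelope peak, and σ_base = 2 gives a rest
  floor ~1.5 % of full scale — roughly a 25 dB burst-to-rest power ratio,
  a clean but not noise-free operating point.

What the generator does **not** model: motor-unit action-potential
physiology, electrode-shift and donning variability, fatigue drift,
powerline interference, inter-subject variability, or gestures with
overlapping channel signatures.  Passing the synthetic benchmark therefore
demonstrates that the pipeline's machinery is correct and that the method
behaves as designed under its own assumptions — not that the accuracy
numbers transfer to recorded human data.

## Preprocessing

Normalization divides by the fixed sensor full scale (128), never a
per-recording maximum: a per-recording scale would be non-causal for
streaming and make train/test scales inconsistent.  Rectification is the
absolute value.  Smoothing is a 4th-order digital Butterworth low-pass,
5 Hz cutoff, applied per channel.

**Causal filtering and the cold-start state.**  The default mode is a
single causal pass (streaming-compatible); zero-phase forward–backward
filtering is available for offline use.  The causal filter's initial state
is step-matched to the mean of the first 160 ms of the rectified signal.
Matching the state to the first *sample* instead leaves a rest-level
transient that rings for ~0.3 s at a 5 Hz cutoff; those windows form an
out-of-distribution pattern at the head of every stream and can emit
spurious early votes.  The 160 ms startup calibration removes this at the
cost of a short non-causal look at stream start only.

**Activity detection.**  The envelope is cut into non-overlapping frames
(default 64 samples = 320 ms); per frame, the periodogram PSD is summed
over channels and averaged over frequency bins, giving a spectral-density
level in dB that is independent of the frame length.  Frames above the
threshold are active; the first-through-last active frame span is the
activity interval.  The threshold default (−55 dB relative to a unit
density reference) is calibrated on the generator's default amplitudes,
where burst frames reach −48…−42 dB and rest frames stay below −65 dB;
the reference level of a dB threshold is hardware-dependent, so both the
threshold and reference are configurable.  When no frame is active the
detector reports "no activity" as a value rather than an exception, so
streaming callers can emit the No-Gesture class.

## Features

Two formulas are implemented exactly as the method defines them, which
differs from common conventions:

- **SSC** is the sum of absolute products of adjacent slopes, not a count
  of sign changes.  It scales quadratically with amplitude.  The
  conventional count is available as `ssc_count`.
- **Hjorth activity** omits mean subtraction: `Σ s²/(N−1)` on the
  rectified (nonnegative-mean) window.  The centered sample variance is
  available as `activity_centered`.

Derivatives for mobility/complexity are first differences.  Variances of
difference vectors use the same `Σ v²/(len−1)` form, with the denominator
floored at 1 so that a 3-sample window (whose second difference has a
single element) remains defined.  A constant-zero window has undefined
mobility and raises; a window whose first difference is exactly zero
yields complexity 0 by convention.  In the vectorized streaming path,
exactly-degenerate windows (possible only on an identically flat signal)
are labeled rest without consulting the classifier.

Windows straddling the activity boundary are excluded from training as
ambiguous; windows fully inside the interval carry the repetition's
gesture label and, optionally, windows fully outside carry label 0.
Flattening is channel-major (all rows of channel 1, then channel 2, …) and
round-trip tested.

## Classifier

Three layers: input 8(l+7), hidden floor(input/2) sigmoid units, one
sigmoid output per class.  The cost is the sum over output units of binary
cross-entropy against one-hot targets, averaged over samples — the
sigmoid-consistent form of "cross-entropy"; scores are per-unit
probabilities and do not sum to 1.  A softmax/categorical variant sits
behind `TrainConfig.loss="softmax_ce"`.  Optimization is full-batch
gradient descent with a fixed learning rate, early-stopped when the
per-epoch cost change falls below `tolerance`; analytic gradients are
verified against central differences to 1e-5 relative.

**Input standardization.**  The feature columns span about four orders of
magnitude (slope-product sums ~1e-4, Hjorth complexity up to tens), which
conditions plain gradient descent so badly that thousands of epochs leave
the benchmark underfit.  `train` therefore fits per-column z-scoring on
the training set by default and stores the affine map in the model, so
inference applies it identically; `standardize=False` restores raw
inputs.  This is the one place the implementation adds a step the original
method statement does not mention, and it is required to make full-batch
gradient descent practical at this input dimensionality.

Class 0 (No-Gesture) is a trained output class: rest windows from the
head/tail of gesture repetitions — and, when the session includes them,
from pure-rest repetitions — carry label 0.  Pure-rest repetitions matter
beyond class balance: the filter cold-start pattern at the head of a
recording otherwise only ever appears inside gesture-labeled activity
intervals, and a classifier that never saw it labeled as rest will vote
unpredictably on it at stream start.

Initialization is seeded uniform in ±0.05 with zero biases; training is
bitwise reproducible given data and seed.  Models serialize to a versioned
JSON container.

## Streaming decision rule

Per-class counters accumulate window votes in stream order; the first
class whose counter *reaches* τ wins ("answering racer" — ties resolved by
arrival order), and an exhausted stream with max count < τ finalizes to
No-Gesture.  The reach comparison is ≥ τ (the operational description of
the rule); a strict > variant is available.  Votes for class 0 count in
N_0, and N_0 reaching τ decides No-Gesture — so a long rest head can
legitimately out-race a weak gesture, which is visible at small window
lengths.  The decision timestamp is the right (exclusive) edge of the
deciding window, the earliest sample at which the decision is causally
computable; response time is signal time from the onset reference
(generator truth, or the activity detector's onset for real data) to that
edge.  Vote counting starts at the first available window — there is no
onset gate — and counters reset between repetitions.

The lower bound on the response is (τ−1)·stride/fs after the first
in-gesture vote; at the defaults (τ = 40, stride 1, 200 Hz) that is
195 ms, which is why decisions arrive a few hundred milliseconds after
onset while gestures last ~700 ms.

## Evaluation conventions

Accuracy is computed over gesture repetitions, with repetitions decided as
No-Gesture counted as errors; pure-rest repetitions appear in the
confusion matrix (row 0) but not the accuracy denominator.  Response times
are averaged over correctly decided repetitions by default, with the
incorrect-decision mean reported separately, because the appropriate
averaging set is application-dependent.  The threshold sweep computes
window-label streams once and replays only the vote layer per τ; this is
exactly equivalent to re-running the full stream because window labels do
not depend on τ (verified by test).

## Benchmark problem sizes

The package's reference benchmark uses 5 gestures + rest with 5 training
repetitions (2 s each) and 10 test repetitions (5 s each) per class,
window 400 ms, stride 5 ms, τ = 40, learning rate 0.5, 400 epochs.  It
trains in about 70 s and evaluates in a few seconds on one CPU.  The
window-size sweep retrains per grid value and is correspondingly more
expensive; the test suite exercises it at reduced size.

## Known limitations

- The SSC and activity formulas are faithful to the method's definitions,
  not to the conventional statistics of the same names; results are not
  comparable with implementations using the count/centered forms.
- The activity detector's frame granularity (320 ms default) pads the
  detected interval with up to one frame of rest on each side, which
  slightly contaminates training labels near the boundary; with small
  windows this is visible, and a smaller detection frame is advisable when
  l < 64 samples.
- Per-unit sigmoid outputs provide no margin calibration; out-of-
  distribution windows can vote arbitrarily, which is why rest patterns
  (including the stream cold start) must be represented in training.
- One gesture per repetition is assumed; there is no multi-gesture
  segmentation, electrode-shift handling, or powerline filtering.
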