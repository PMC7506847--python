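# Methods

## Problem and signal model

Pre-impact fall detection must fire during the 200–400 ms between loss of
balance and ground impact.  The physical signature is *slight
weightlessness*: once the feet unload, the ground reaction force no longer
balances gravity, and the acceleration sum vector magnitude
`SVM = sqrt(ax² + ay² + az²)` (units of g) declines from ~1 g into the
0.6–0.9 g range while trunk angular velocity stays comparatively low.
Everything in this package operates on 6-channel IMU traces — tri-axial
acceleration in g, tri-axial angular velocity in °/s — sampled uniformly
(50 Hz is the reference rate; all window sizes scale as `round(d·fs)`).
Units are fixed at the I/O boundary: m/s² and rad/s inputs are converted
on read, never downstream, because every detector threshold is quoted in
g and °/s.

## Classifier

The network is a deliberately small 1D CNN: three valid (unpadded)
convolutions with 32/64/128 output channels and kernel length 3, ReLU
activations, max pooling (kernel 2, stride 2) after the first two conv
layers only, global average pooling (GAP), and one linear layer to two
logits.  The first convolution spans all six input channels (early
fusion).  Leaving the third conv layer unpooled preserves a temporal
sequence `S_k(x)` for activation mapping; with a 100-sample input the
temporal lengths are 100 → 98 → 49 → 47 → 23 → 21, so L = 21.  The GAP
head makes the classifier and the CAM construction independent of the
exact value of L, which is therefore treated as a derived property of the
padding/pooling choices rather than a constant.

GAP is implemented as the temporal *mean* `f_k = mean_x S_k(x)`.  A
sum-pooling convention differs only by the constant factor L, which the
head weights absorb; the mean keeps the CAM identity clean:
`mean_x M_c(x) = g_c − b_c` (asserted to 1e-5 in the tests).

Training uses Adam (lr 1e-4, β = 0.9/0.999), batch size 4, cross-entropy,
and a stratified 2.3:1 train/test split with a seeded shuffle.  Epoch
count is a free parameter (default 50; the desk-scale experiments use
20, which is already past convergence on the synthetic corpus — held-out
accuracy plateaus at 100% within ~5 epochs).  When a validation set is
given, the best-validation-accuracy parameters are restored after
training.  Inputs are standardized per channel with training-set
statistics stored in the checkpoint; this only shifts/scales the six
channels (acceleration ~1 g vs. gyro ~100 °/s) and leaves the CAM algebra
untouched.  Forward, backward (verified against central differences to
~1e-10) and Adam are hand-implemented on NumPy arrays; the model has
~32k parameters and trains at roughly 0.3 s/epoch per 100 windows on one
CPU core.

Class encoding: index 0 = non_fall, 1 = fall; fall is the positive class
in every metric.

## Class activation mapping

`M_c(x) = Σ_k w_kc · S_k(x)` is computed from the retained feature maps
and head weights — no gradients involved.  For display the raw map is
min-max normalized to integers 0..255 (round half up; a constant map
carries no localization information and maps to all zeros) and upsampled
to the input length by linear interpolation on positions spanning
`[0, target_len − 1]` (endpoints preserved, re-rounded); nearest-neighbor
upsampling is available for exact step plots.  "Highlighted" regions are
maximal runs at or above an intensity threshold, default 200/255.  The
threshold defining "yellow" is a visualization parameter, exposed, never
baked into scientific claims.

## Threshold detector

The streaming detector consumes one frame at a time and keeps three
states: *waiting* (must first see SVM ≥ 0.95 g), *armed*, and
*evaluating*.  A falling-edge crossing (previous frame ≥ 0.95 g, current
< 0.95 g) starts a candidate at the current frame; the evaluation window
is the n = `round(0.4·fs)` frames beginning there, and the verdict —
fall iff at least `ceil(0.5·n)` frames jointly satisfy
SVM ∈ [0.6, 0.9] g (inclusive) and gyro < 100 °/s (exclusive) — becomes
available exactly at `start_frame + n`, i.e. 400 ms latency at any rate.
Design choices made where the rules were genuinely open:

* the two per-frame conditions are required jointly (they are cumulative
  features of the early-fall phase);
* band edges inclusive, gyro threshold exclusive (a tie-break; no
  inclusivity is implied by the calibration);
* the start trigger is an edge, not a level: a level test would re-arm on
  every sub-threshold frame;
* after any verdict the detector re-arms only once SVM has returned to
  ≥ 0.95 g, so one contiguous excursion raises at most one alarm and
  window overlap is impossible;
* the gyro feature is the full 3-axis norm — rotation-invariant and the
  conservative reading of a single scalar threshold.

Streaming and whole-trace processing are equivalent by construction and
asserted in tests.  Widening the band or raising the gyro limit can only
increase qualifying counts (monotonicity, also tested).

## Synthetic data generator

The generator emulates a staged-protocol corpus: waist-mounted sensor,
y-axis along gravity, 50 Hz, four fall directions plus walking, jogging,
standing up and lying down (jumping and quiet standing are also
available).  Signals are piecewise-smooth SVM/gyro envelopes (cosine
ramps between phase levels), decomposed onto axes via a seeded body-tilt
and azimuth model (falls tilt to 60–85° from vertical; direction only
redistributes the horizontal component), plus Gaussian measurement noise.

**Noise is band-limited.** White per-axis noise (σ_acc = 0.02 g,
σ_gyro = 5 °/s) is passed through a 3-tap moving average (per-frame σ
≈ 0.012 g), emulating the low-passed stream that on-device filtering
delivers to a deployed detector.  Unfiltered white noise at this
amplitude would produce isolated spurious 0.95 g crossings during quiet
standing — artifacts of the simulation, not of filtered hardware — that
corrupt the falling-edge trigger semantics.  The optional per-channel
Kalman smoother in `imu` is therefore OFF by default: generated data
already reflect a filtered stream.

Fall envelope, in order: standing at 1 g (1.2–2 s); a 3-frame trigger
ramp through 0.95 g (the first sub-0.95 g frame is `fall_start_frame`);
the weightless core — `round(weightless_s·fs)` frames declining from
min(0.88, plateau+0.08) to the plateau level with a small 4–8 Hz
fluctuation, floored at 0.615 g — labeled `early_fall`; a pre-impact
plunge (0.24 s cosine decline to 0.52 g) as the body accelerates toward
the ground; the impact spike (3–6 g, 0.06 s) and recovery at 1 g.
Default sampling ranges: plateau 0.6–0.9 g, weightless duration
0.14–0.24 s (7–12 frames at 50 Hz), early-fall gyro envelope peak
20–80 °/s (reached only at contact, so early-fall gyro stays well below
100 °/s).  The `early_fall` label deliberately covers exactly the
weightless core; the plunge is part of the impact phase (the fall is
already ballistic).  Ground contact, where needed for scoring, is the
SVM argmax, not a label.

The corpus is *detectable by construction*: the in-band dwell time after
the 0.95 g crossing (trigger tail + core + plunge-through-band) exceeds
10 frames for essentially every profile draw, so the half-rule fires,
while every ADL violates at least one condition by design — walking and
jogging dips are 2–3-frame notches with shoulders at 1 g (< 0.1 s below
0.95 g); jumps pass the band only transiently on the way to a < 0.6 g
flight phase; lying down declines through the band but with trunk
rotation held above 100 °/s over the entire sub-0.95 g excursion;
standing up never leaves 0.9 g.  Consequently the synthetic end-to-end
experiment scores near-perfectly (~99–100% sensitivity/specificity).
This is what passing tests demonstrate: internal consistency between the
calibrated thresholds and the stated signal characteristics — not
field performance.  Real falls include hard cases the defaults exclude
(early-phase SVM below 0.6 g, near-falls, syncope; an FN mode
reproducible via `FallProfile(plateau_g≈0.55)` is configurable but off
by default), and real ADLs are far more diverse.

All randomness flows from explicit integer seeds through
`numpy.random.Generator`; per-trace seeds are spawned from the corpus
seed via `SeedSequence`, so corpora regenerate byte-identically.

## Evaluation

Trial-level scoring treats a fall trial as detected when any fall verdict
occurs — by default (for synthetic data, where ground contact is
knowable) only verdicts landing no later than the contact frame count,
since pre-impact timing is the method's point.  Metrics are computed with
exact rational arithmetic and rounded half-up to two decimals, matching
the reference tables' printed precision: e.g. TP/FN/TN/FP = 142/9/103/3
→ 95.33% accuracy, 94.04% sensitivity, 97.17% specificity, and
207/12/222/8 → 95.55% accuracy.  A metric whose class is absent is
reported as undefined, never as 0.

## Problem sizes and numerical choices

The shipped experiments use corpora of 151/106 and 200/200 trials,
a ~300-window training set with 20 epochs, and 500-trace population
statistics — sizes chosen so the full suite and the acceptance script
each complete in well under a minute while keeping binomial noise on the
percentage metrics below ~2 points.  Tolerances: CAM vs. brute-force
oracle 1e-10 (identical arithmetic reordered), CAM/logit identity 1e-5
(float32-safe), norm oracles 1e-12.  Degenerate inputs are errors, not
silent defaults: empty traces, single-class training sets, windows that
overrun a trace, out-of-range class indices.

## Known limitations

* The simulator is phenomenological (envelope + noise), not biomechanical;
  it cannot generate near-falls, syncope, stumble recoveries, or sensor
  artifacts (drift, clipping, dropout).
* The MobiAct adapter documents the expected file layout and converts
  units but is exercised only on a synthetic stand-in file.
* The detector evaluates one candidate at a time; a second fall within
  400 ms of a first candidate's start is folded into that window.
* At sampling rates other than 50 Hz the window scales as `round(0.4·fs)`
  frames, but the band/gyro thresholds themselves were calibrated at
  50 Hz.
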