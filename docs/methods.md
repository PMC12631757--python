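# Methods

`hhtsann` classifies multichannel resting-state EEG epochs into major
depressive disorder (MDD) vs healthy control (HC) with a network whose first
stage is the Hilbert-Huang Transform (HHT), followed by squeeze-and-excitation
(SE) channel recalibration, single-head temporal self-attention and a softmax
head. Evaluation uses Leave-One-Subject-Out (LOSO) cross-validation, and a
grouped KernelSHAP analysis quantifies how much of the decision rests on the
HHT-derived feature planes relative to the raw signal planes. This note
records the model, its assumptions, the defaults, the numerical choices, and
what the synthetic test bed does and does not demonstrate.

## Signal model and epoching

A recording is a channels x samples matrix in microvolts with its sampling
rate, 10-20 electrode labels and one class label per subject. Epochs are cut
by a sliding window; the canonical setting is a 4-s window at 256 Hz (1,024
samples) with no overlap. The step is a parameter, not a constant: overlap
choices vary between studies and change only the epoch count, never the
window length. Coordinates are 0-based and half-open; epoch `k` covers
samples `[k*step, k*step + window)`. An ECG lead, when present, is excluded
from model input by default (`drop_ecg`); the model is a scalp-EEG
classifier. Each epoch-channel trace is z-scored (std clamped at 1e-12, so a
constant trace maps to zero) before feature extraction, which removes
inter-subject amplitude offsets that a clinical amplifier montage does not
control.

## Empirical Mode Decomposition

Each channel trace x(t) is decomposed as

    x(t) = sum_{i=1..N} IMF_i(t) + r(t)

by sifting: subtract the mean of the upper and lower natural-cubic-spline
envelopes through the strict local maxima/minima until the Cauchy criterion
`SD = sum(m^2)/sum(h^2) < 0.2` (m the subtracted envelope mean) or 100
iterations; then peel the mode off and repeat until the residual has fewer
than four extrema or is monotone. Numerical choices:

- **Envelopes**: natural cubic splines; the two extrema nearest each end are
  mirrored across the signal edge to tame end swings.
- **Plateaus** report their midpoint index; endpoints are never extrema;
  all tie-breaks are deterministic, so the decomposition is bit-reproducible.
- **Completeness** holds by construction — the residual is the input minus
  the IMF sum — so reconstruction error is pure float accumulation
  (measured < 1e-12 relative; asserted < 1e-8 over 100 signals).
- **Stopping**: the classical SD = 0.2 default leaves a minority of "riding
  waves", so sifted modes satisfy the strict IMF definition
  (|#extrema - #zero-crossings| <= 1) only approximately (~70-85% on white
  noise). An opt-in `enforce_imf_criterion` keeps sifting until the counts
  reconcile, which brings compliance to ~100% at a modest cost in iterations.
  The default stays at the plain Cauchy stop because deeper sifting
  progressively drains physical amplitude modulation out of the modes.
- **Depth**: `max_imfs = 4` by default for a fixed network tensor shape;
  electrodes yielding fewer modes contribute zero-padded planes. Library
  callers may raise the depth.

## Hilbert spectral stage

Each IMF is lifted to its analytic signal h(t) (FFT construction: negative
bins zeroed, positive doubled), giving instantaneous amplitude |h(t)| and
instantaneous frequency

    f(t) = (1/2pi) d theta/dt,

with theta the unwrapped phase and the derivative taken by central
differences (one-sided at the ends). Frequencies are clipped to [0, fs/2]:
excursions outside the physical band are numerical artifacts of the discrete
derivative near low-amplitude samples, and clipping makes the feature range
predictable for the network. Validation against closed forms (tones, linear
chirps, AM laws) excludes 32 samples at each end, where the discrete Hilbert
transform has edge bias; the features themselves keep full length. Measured
accuracy on the oracles: < 1e-3 Hz interior error for a 10 Hz tone, ~0.4 Hz
interior RMSE for a 1->30 Hz chirp over 4 s at 256 Hz.

## Feature map and network

Per epoch, the feature matrix stacks, column-wise and electrode-major, the
z-scored raw trace of each electrode plus amplitude and frequency planes for
each of `max_imfs` IMFs: C' = n_electrodes x (1 + 2 max_imfs) columns. The
raw planes are part of the model input so that the raw-vs-HHT attribution
comparison is well-posed; `include_raw=False` gives the HHT-only variant.
The temporal axis is average-pooled by `time_pool` (default 16; a 1,024-
sample window becomes T' = 64 steps) so T x T attention stays cheap on a
CPU; alpha-band amplitude dynamics survive 16x pooling comfortably since
the planes are near-baseband envelopes, not the raw oscillation.

The network is:

- **Squeeze**: z_c = mean_t F(t, c).
- **Excite**: s = sigmoid(W2 relu(W1 z)), bottleneck C'/r with r = 4;
  no biases, so zero weights give the neutral gate s = 1/2.
- **Scale**: F~(t, c) = s_c F(t, c) — a contraction, since s in (0, 1).
- **Attention**: single-head scaled dot-product over time,
  A = softmax((F~ Wq)(F~ Wk)^T / sqrt(d)) (F~ Wv), d = 32 by default.
- **Head**: global average over time, dense layer to two logits, softmax
  over (HC, MDD); MDD is the positive class.

EMD sifting is not differentiable, so the HHT stage is a fixed transform
computed inside the forward pass; learning is confined to the SE, attention
and head parameters. Gradients for those are implemented by hand in numpy
and verified against central finite differences (relative error < 1e-2 at
sampled coordinates; in practice ~1e-5). Initialisation is uniform fan-in
scaling, seed-controlled; feature columns are standardised with statistics
fitted on the training split only, and the statistics travel with the
checkpoint. Forward passes are deterministic: two passes agree bitwise.

## Training and LOSO evaluation

Adam (lr 1e-3, batch 64, max 50 epochs) minimises cross-entropy with
optional inverse-frequency class weights (on by default; clinical epoch
counts are imbalanced). Early stopping monitors validation loss with
patience 5 and restores the best-validation parameters; `patience = 0`
trains exactly one epoch, and an empty validation set disables early
stopping. One fold per subject: the test fold holds all and only that
subject's epochs; within each fold 10% of the *training subjects* (at least
one) form the validation split, so no subject's epochs ever straddle the
train/validation/test boundary. Folds whose training slice lacks a class are
skipped with a warning. Confusion counts are pooled across folds for the
headline sensitivity/specificity/accuracy; fold-averaged percentages are
reported alongside, since the two conventions differ in general.

## Shapley attribution and the ratio R

KernelSHAP with a single randomly chosen background epoch and (by default)
10 target epochs, at plane granularity: each raw channel plane and each
IMF amplitude/frequency plane is one feature group, masked by replacing the
whole column with the background's values. The weighted least-squares system
uses the Shapley kernel with the efficiency constraint eliminated
analytically, so local accuracy (attributions summing to
f(target) - f(background)) holds on every run. All 2^M - 2 proper coalitions
are enumerated whenever they fit the budget (always for M <= 12, where the
estimate is exact — verified against brute-force enumeration to ~1e-15);
otherwise complete coalition-size classes are enumerated from the extremes
inward and the remainder sampled. The single-background design is cheap but
high-variance; a multi-target average tempers it, and the explanation seed
controls both the background/target draw and the coalition sample.

R is the mean |SHAP| over HHT planes divided by the mean over raw planes;
R > 1 means the HHT representation dominates the decision. When the raw-side
mean is at solver-noise scale the report carries a `dominant` flag, since
the ratio's magnitude is then unreliable.

## Synthetic cohorts

The generator emulates resting EEG as 1/f-filtered Gaussian background
(exponent 1.0, sd 10 uV) plus narrowband-filtered noise oscillations in the
delta/theta/alpha/beta bands (amplitudes 20/10/15/5 uV), with a lognormal
per-subject amplitude jitter (sigma 0.10) so subjects are not statistically
identical. The class contrast multiplies the MDD alpha amplitude by
`class_effect` (default 2.0, i.e. a 4x alpha power ratio). Defaults mirror
the clinical protocol the package targets: 34 MDD / 30 HC subjects, 19
scalp channels, 256 Hz, 2-minute segments. Everything is bit-reproducible
under (seed, subject index).

What this test bed shows: that the pipeline recovers a known band-power
class signal through EMD + Hilbert features, that LOSO hygiene holds, that
label permutation destroys performance, and that attribution correctly
locates the signal in the HHT planes. What it does not show: performance on
clinical EEG — real depression effects are far subtler than a doubled alpha
amplitude, and the generator has no artifacts (blinks, EMG), no
volume-conduction correlation structure across electrodes, and no
nonstationary state changes within a recording.

## Problem sizes used by the automated checks

The pipeline-level checks run a 16-subject cohort (8/8), 4 channels at
128 Hz, 48 s per subject, 4-s windows (192 epochs), with a reduced network
(3 IMF planes, d = 16, 16x pooling): large enough for the class effect and
the permutation null to be measurable, small enough to run on one CPU in a
few minutes. The permutation null is assessed at the subject level
(majority vote per held-out subject) because LOSO predictions are clustered
by subject — epochs of one subject are not exchangeable units — and it
pools ten label shuffles to stabilise the permutation estimate.

## Known limitations

- EMD here is the classical single-channel algorithm: no ensemble (EEMD/
  CEEMDAN) noise stabilisation and no multivariate mode alignment across
  electrodes, so mode mixing can occur on broadband signals.
- The number of IMFs is signal-dependent; fixing the tensor shape by
  pad/truncate at `max_imfs` discards modes beyond the depth (slow trends
  end up in the residual, which is not a feature plane).
- The attention stage sees pooled time steps; phenomena faster than the
  pooling window are represented only through the amplitude/frequency
  envelopes.
- Checkpoints store plain float64 arrays; no quantisation or
  GPU-specific paths — the model is deliberately small enough for CPU.
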