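# Methods

## Problem setting

During overt speech production, sensors over speech-related cortex show
elevated-amplitude MEG activity that begins slightly before the acoustic
output. `neurovad` exploits this to label every millisecond of a trial's
production window as Speech or Non-Speech from the neural data alone. The
acoustic channel provides ground truth for training and evaluation; at use
time the predictor is causal and needs no audio.

## Protocol and data model

Trials follow a time-locked delayed overt-reading task: 0.5 s baseline, 1 s
phrase stimulus, 1 s preparation (fixation), then a 2 s production stage
cued by fixation offset. Epochs span −0.5 to 4.5 s around stimulus onset;
only the 2 s production window is analyzed. All analysis runs at 1 kHz so
one sample is one millisecond, the labeling resolution; higher acquisition
rates (e.g. 4 kHz) are polyphase-resampled (zero-phase) before denoising,
which also makes the 2-level wavelet approximation band (see below) line up
with the stated <125 Hz target.

Sample indexing is 0-based half-open internally; every user-facing boundary
uses the 1-based inclusive millisecond convention in which the detected
onset is the **last Pre-Speech** sample and the offset the **last Speech**
sample. The worked fixture (voicing at ms 402–931 of a 2000 ms window,
hence onset 401 / offset 931) pins this convention, and conversions happen
only at reporting boundaries.

## Synthetic sessions

The generator emulates what the pipeline consumes — sensor amplitude
statistics — rather than cortical physiology:

- **Background**: per-sensor low-passed white noise (4th-order Butterworth,
  default 100 Hz) normalized to unit variance, plus a rank-3 shared
  background (default weight 0.3) standing in for common-mode fields. Real
  inter-sensor covariance is richer; nothing downstream depends on it.
- **Speech effect**: a random subset of sensors (default 15%) is
  amplitude-scaled by `10**(snr_db/20)` between (acoustic onset −
  `neural_lead_ms`) and the acoustic offset, with 10 ms raised-cosine ramps.
  The default lead is 10 ms (speech-motor activity precedes voicing).
- **Acoustics**: the microphone channel is unit white noise plus a burst
  exactly over the speech span. The burst carrier is a harmonic complex
  (f0 = 150 Hz, 1/k roll-off, lightly jittered phases with a glottal-pulse-
  like maximum at the burst start) plus a weak noise floor — the
  quasi-periodic structure of voiced speech. Its short-time power is far
  steadier than white noise, which is what gives real voicing a
  well-defined acoustic edge; a pure white-noise burst would make
  millisecond-accurate onset detection information-theoretically marginal
  at 10 dB. `audio_snr_db` can decouple the acoustic SNR from the neural
  one (used to study the no-neural-signal regime with intact labels).
- **Timing**: onset jitter uniform 300–600 ms after the production cue,
  duration uniform 400–900 ms — everything fits the 2 s stage, matching
  natural phrase-reading latencies and lengths.
- **Artifacts**: a configurable fraction of trials (default 0.25, the
  typical visual-inspection rejection rate for this task) receives a 100 ms
  Hann transient of 25× baseline standard deviation on a quarter of the
  sensors — the jaw-clench class of artifact, far above any task effect.

Passing tests on these sessions shows the pipeline's logic and bookkeeping
are correct under known ground truth; it does not certify performance on
real MEG, where effects are weaker, nonstationary and correlated.

## Preprocessing

1. **Gradiometer selection** — planar gradiometers suppress distant noise;
   magnetometers and auxiliary channels are excluded from the sensor
   matrix (audio is carried alongside each epoch).
2. **Bad channels** — a channel is unresponsive if its pooled variance is
   below `flat_threshold` (default 1e−12), noisy if its robust variance
   (squared scaled MAD) exceeds 25× the median across channels. Decisions
   are made once per session and applied to all trials; channel order is
   preserved.
3. **Artifact-trial rejection** — the statistic is the peak, over sensors
   and time, of a 100 ms moving-RMS envelope in robust-z units (per-sensor
   median/MAD pooled over the session). The envelope is the deliberate
   choice: raw per-sample peaks of a few-times-elevated *sustained* speech
   signal reach z ≈ 14 over a 5 s epoch purely from Gaussian extremes,
   whereas envelope amplitudes separate cleanly (baseline ≈ 1.2, speech
   elevation ≈ 3.5, artifact transients ≈ 15 at the generator's settings),
   so the default threshold 10 rejects exactly the artifact class. Session
   statistics are computed on a deterministic time-subsample (≤ ~500k
   samples per channel) — medians and MADs are insensitive to this.
4. **Wavelet band restriction** — each channel is decomposed to level 2
   with db4, the detail coefficients are zeroed, and the signal is
   reconstructed from the approximation, restricting content to <125 Hz
   (high gamma and below) at 1 kHz. Boundary handling uses the *periodized*
   DWT: it makes the operator an exact orthogonal projection, so denoising
   is idempotent to machine precision and repeated application is harmless.
   (Symmetric extension, the other common choice, leaves the operator
   non-projective with ~10% edge deviation on reapplication.) A
   soft-threshold variant (universal threshold, noise scale from the finest
   detail band) is available behind `soft_threshold=True`.
5. **Production window** — the final 2 s of each epoch, starting at the
   production cue; audio is cut identically.

## Acoustic labeling

The microphone channel can be denoised with a single-pass spectral Wiener
filter (noise spectrum from the trial's initial silence; gain floor 0.05,
exponential gain smoothing 0.6). The onset/offset detector operates on the
raw trace by default — its noise-floor reference (median short-time energy
of the first 200 ms) is self-calibrating, which a spectral gate would
distort.

Detection is two-stage:

1. **Coarse**: 10 ms centered short-time energy; frames above 3× the noise
   floor are speech candidates. Supra-threshold blips shorter than 30 ms
   are discarded as noise; remaining runs separated by less than 250 ms are
   bridged (intra-phrase pauses are part of the phrase and are not
   predicted); runs shorter than 100 ms are discarded. No surviving run
   raises a "no voice detected" flag and the trial is dropped, mirroring
   untimely-articulation rejection.
2. **Refinement**: each boundary is moved to the crossing of the half-rise
   level (midpoint of noise floor and the median speech energy) by a short
   5 ms centered energy window. A centered window crosses the mid-level
   when it is half inside the voiced span, so the estimate is unbiased in
   both the window length and the SNR — the property that lets the
   detector meet a ±5 ms onset contract at 10 dB.

`label_segments(onset, offset, T)` then emits the exact partition
Pre(1..onset) / Speech(onset+1..offset) / Post(offset+1..T); the binary
labels are always re-derived from the three-way ones (`offset == T` leaves
an empty Post segment, a documented edge case).

## Features

Per time point across the S retained sensors: F1 = Σ|x|, F2 = RMS,
F3 = population standard deviation, F4 = argmax |x| (1-based; ties to the
lowest index). The population convention for F3 makes F2 ≥ F3 exact, with
equality iff the cross-sensor mean vanishes. F1 and F3 are strongly
correlated but not redundant; `feature_difference` exposes their
z-scored difference. For model input, F1–F3 are z-scored per trial and F4
is scaled to (0, 1] by S (`scale_f4=False` feeds the raw index). Segment
RMS features are the per-sensor RMS over each labeled segment, with
Non-Speech defined over the pooled Pre and Post samples.

## Models

**SVM sanity check.** Per-segment RMS vectors, 2nd-order polynomial kernel
SVM — implemented as the inhomogeneous kernel (x·y + 1)², since the
homogeneous variant (coef0 = 0) cannot represent affine separation —
stratified 6-fold cross-validation, feature standardization fit on training
folds only. Pairings: Pre-vs-Post, Pre-vs-Speech, Post-vs-Speech,
Speech-vs-NonSpeech, and 3-class with one-vs-one voting.

**LSTM sequence labeler.** Two unidirectional LSTM layers (gates ordered
input/forget/cell/output; hard-sigmoid gate activations clip(0.2x+0.5, 0, 1);
tanh cell and state activations), a 2-unit fully connected layer and
softmax, trained with per-sample cross-entropy via BPTT and Adam
(β₁ = 0.9, β₂ = 0.998, ε = 1e−8), global L2 gradient-norm threshold 0.1,
learning rate 0.005 (midpoint of the 0.004–0.006 search range), at most
500 epochs. The implementation is pure numpy with an analytically derived
backward pass, verified against numeric directional derivatives to ~1e−9
relative error. Defaults follow the published recipe (256 hidden units per
layer); desk-scale runs use smaller settings, see "Problem sizes".

Design choices where the recipe is silent:

- **Validation split**: 20% of training trials (seeded) are carved out; the
  returned parameters are those of the best-validation-accuracy epoch (the
  "epochs decided on validation performance" rule), with patience-based
  early stopping.
- **Input**: the per-sample 4-vector only, no context window — the features
  are already cross-sensor aggregates and the recurrence carries history.
- **Class imbalance** (Speech ≈ 25–35% of samples): plain cross-entropy;
  no reweighting is applied by default.
- **Direction**: unidirectional only in the training/prediction path — the
  real-time claim requires causality.
- **`time_stride`**: features may be averaged over non-overlapping blocks
  (labels take the block majority) before the recurrence, and predictions
  are repeated back to sample rate. Stride 1 is the reference
  configuration; strides of a few ms trade boundary resolution for an
  n-fold cut in compute and are what the scaled test runs use.
- Forget-gate biases initialize to 1 (standard gradient-flow trick);
  other biases to 0; weights Glorot-uniform.

Models serialize to `.npz` with exact float arrays, embedded config and
training history; reloaded models predict bit-identically.

## Evaluation

Per-sample confusion counts with Speech positive; accuracy
(TP+TN)/(TP+TN+FP+FN); precision/recall pooled across trials
(micro-average — counts summed before the ratio), since single
cross-subject values are the quantity of interest; per-trial accuracy
lists with per-subject mean/std/median. Undefined ratios (no positive
predictions or truths) are NaN, never silently 0. Predicted onset/offset
are read from the **longest** predicted Speech run (robust to isolated
flipped samples; a first-run rule is available). The most-active-sensor
mode analysis counts F4 values within speech-labeled samples per subject
and pooled. One-tailed paired t tests use the exact Student distribution;
identical samples give p = 0.5 by convention.

A note on onset bias: with a constant neural lead and a calibrated
label-trained model, the cross-entropy-optimal decision boundary coincides
with the label boundary — the network simply learns the lead — and the
residual timing error is a few milliseconds *late* (majority-class prior
plus stride quantization), not early. An early-onset bias of the kind seen
on real recordings reflects properties of real data (variable lead,
boundary-adjacent planning/feedback activity) that the generator does not
emulate; the synthetic end-to-end check therefore bounds the magnitude of
the onset error rather than asserting its sign.

## Numerical choices and degenerate inputs

- Detector: noise floor gets a 1e−300 guard; a degenerate voiced span
  (offset ≤ onset) raises the no-voice flag; `onset` is floored at 1.
- Wiener filter: zero audio returns zero; bins with zero power get zero
  gain through the 1e−300 guard.
- `label_segments` validates 1 ≤ onset < offset ≤ T strictly.
- F4 tie-break: lowest sensor index (numpy argmax), deterministic.
- Feature z-scores of constant signals are zero, not NaN.
- All randomness (generator, splits, initialization, batching) flows from
  explicit integer seeds; training is bit-reproducible run to run.

## Problem sizes

The reference configuration of the study protocol is 5 stimuli × 100
trials per subject at 200 gradiometers. The test suite and the scaled
end-to-end checks run: 2 subjects × 5 stimuli × 60 trials (50 training
trials per stimulus, the protocol's split) at 10 dB with a 24-unit,
stride-5 network and ≤ 40 epochs — chosen so a full run completes on one
CPU core in minutes while leaving the learning problem non-trivial; the
null check (snr 0 dB with intact acoustics) uses one subject. Artifact
injection is disabled in those runs so the 50-trial training budget is met
exactly; the rejection stage is exercised separately at the 25% rate.
Hidden-size and stride scaling were verified not to change any qualitative
conclusion (the full-size configuration remains the default).

## Known limitations

- The generator's independence and stationarity assumptions understate
  real MEG structure; accuracies near 1 on synthetic data say nothing
  quantitative about real subjects.
- The acoustic detector's contract (±5 ms onset, ±10 ms offset at 10 dB)
  is calibrated to the generator's burst model; real microphone audio has
  breathy onsets and pre-voicing that widen it.
- No ICA/tSSS/SSP artifact correction, no head-movement compensation, no
  source modeling: sensor-space only.
- The 3-class SVM and Pre-vs-Post discrimination depend on segment-length
  and boundary cues in the synthetic world; their absolute values are not
  comparable to real-data results.
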