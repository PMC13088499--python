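# Methods

This note documents the models, algorithms and default parameters behind
`mibci`, the design choices made where several reasonable options existed,
and what the synthetic-data generator does and does not capture about real
EEG.

## The decoding problem

A motor-imagery (MI) brain-computer interface maps short windows of
multichannel EEG onto a small set of mental classes — here `rest`,
`left_mi`, `right_mi` — and turns the class-probability stream into
continuous and binary control signals for a game or effector. The
physiological signal is event-related desynchronization (ERD): imagining a
hand movement attenuates alpha (8–12 Hz) and beta (15–30 Hz) band power over
the contralateral sensorimotor cortex (C3/C4 and neighbours). Everything in
the pipeline exists to make that band-power modulation detectable in single
1 s windows, online, on a 24-channel mobile recording contaminated by
blinks, muscle activity and 50 Hz line noise.

## Synthetic data generator (`mibci.synthdata`)

The generator produces seeded recordings with the statistical structure the
pipeline assumes:

* **Paradigm timing.** Per trial: 3 s break → 1 s cue → 3 s task, so task
  onsets are 7 s apart. Cue markers carry the on-screen symbol
  (`arrow_left`, …); task-onset markers (`task:<symbol>`) sit at cue offset,
  where imagery begins. A 15 s lead-in leaves room for the offline 10 s head
  crop.
* **Background.** Per-channel Gaussian noise spectrally shaped to
  PSD ∝ 1/f^β (β = 1 by default), scaled to 8 µV RMS.
* **Oscillations.** 10 Hz alpha (10 µV) and 20 Hz beta (5 µV) sinusoids with
  per-channel random phase. During a task interval of class *c* the
  oscillation amplitude at channel *ch* is multiplied by
  `1 − erd_depth[(c, ch)]`; band *power* therefore scales by `(1 − d)²`,
  matching the band-specific nature of ERD (the broadband background is not
  attenuated). Defaults attenuate contralateral motor channels (C4/CP6/FC6
  for left-hand MI, C3/CP5/FC5 for right) by 0.5 at the primary site and 0.3
  at the neighbours.
* **Artifacts.** Blinks: a smoothed biphasic ~300 ms pulse, 150 µV at the
  virtual Fpz position, decaying exponentially with scalp distance; Poisson
  rate 6/min. Muscle bursts: 500 ms of >30 Hz band-limited noise at 5×
  background RMS near T7/T8, 2/min. Line interference: a common 2 µV 50 Hz
  sinusoid. The calibration generator forces all artifact rates, markers and
  ERD to zero — the "sit still for one minute" segment ASR fitting needs.
* **Determinism.** All randomness flows from one `numpy` generator seeded by
  `SimConfig.seed`; identical configurations give bit-identical recordings.

What it deliberately does **not** emulate: volume conduction / realistic
forward models, non-stationary amplitude drift, inter-subject variability,
imperfect task compliance, or electrode impedance changes. Passing the
synthetic recovery tests therefore shows the pipeline is *correct and
sensitive* (it finds band-power modulations of realistic size under
realistic artifact load), not that any particular accuracy transfers to
real recordings.

Sample sizes used in the test suite follow the study conditions: the
classification-recovery benchmark uses 40 trials per class at ERD depth 0.6,
and the offline/online equivalence check replays a ~120 s recording.

## Preprocessing (`mibci.preprocess`)

Order of operations: band-pass filter → head crop (offline) → channel
rejection (offline) → artifact subspace reconstruction → common average
reference → epoching → baseline correction → per-session normalization.

### Band-pass filter

An IIR Chebyshev type 2 band-pass, 4–36 Hz, overall order 16 (8 second-order
sections), realized in two causal stages:

1. the forward IIR with persistent per-section state;
2. a matched linear-phase stage whose taps are the time-reversed impulse
   response of the same IIR, truncated at a fixed latency D = 0.5 s and
   tapered with a half-cosine toward the truncated end.

Stage 2 approximates `z^-D · conj(H)`, so the cascade has the
magnitude-squared (zero-phase) response delayed by exactly D: the measured
mean group delay over 8–30 Hz is 499.9 ms with <1 % ripple — an almost
constant half-second delay, which is the methodological latency the online
system pays. A causal IIR alone cannot have this property (its passband
delay at these design parameters is 20–120 ms and strongly
frequency-dependent), which is why the linear-phase realization is the
default; `zero_phase=False` exposes the bare causal IIR.

The stopband attenuation is not a free user knob in practice: 40 dB is
frozen as the default after a design scan over 20–60 dB — it gives the
flattest group-delay profile over 8–30 Hz and, because the cascade squares
the magnitude response, ~80 dB rejection at 50 Hz. No notch filter is used;
the 50 Hz bound is enforced on the band-pass response itself. The
half-cosine taper exists to suppress the Gibbs overshoot of the hard
truncation (without it the realized response peaks at +0.6 dB near 6.5 Hz;
with it the gain is ≤ 1 everywhere).

Chunked streaming output is bit-identical to batch output because both
stages are sequential recursions with carried state. Offline, the fixed
0.5 s latency is compensated by advancing the filtered signal before
epoching; online it simply exists, as on the live system.

### Channel rejection

Channels are dropped when they are flatlines (SD < 0.1 µV), excessively
noisy (robust SD > 5× the median robust SD across channels), or carry
non-physiological spikes (>500 µV absolute). The thresholds are repository
defaults for the three artifact categories; only the categories themselves
are externally fixed.

### Artifact subspace reconstruction (ASR)

Calibration (≥30 s of artifact-light data, band-passed like everything
else) yields: the Euclidean average of 0.5 s windowed covariances, its
eigenbasis, and per-component RMS mean/SD across windows. The rejection
threshold per component is `mean + k·SD` with k = 3 — deliberately
aggressive; `threshold_k` is exposed for the conventional 10–20 range.

At apply time each 0.5 s window is eigendecomposed (PCA), which concentrates
spatially coherent artifacts such as blinks into few directions. A window
direction `v` with variance `d` is flagged when
`sqrt(d) > edge · sqrt(Σ_i (t_i · (u_i·v))²)`, where `u_i, t_i` are the
calibration directions and thresholds and
`edge = 1 + sqrt(n_channels / n_samples)` corrects for the finite-sample
inflation of leading sample eigenvalues (the Marchenko–Pastur edge): the
calibration RMS statistics are measured in a fixed basis and do not see the
selection bias that per-window PCA introduces, so without the correction
clean data would be flagged systematically. The flagged subspace is
reconstructed from the retained directions through the calibration
covariance square root M: `X' = M · pinv(keep ∘ (VᵀM)) · Vᵀ X`. With nothing
flagged the window passes through untouched (exact identity), and at most
`max_dropout_fraction = 0.4` of the directions are repaired per window —
worst offenders first; windows that would exceed the cap are partially
repaired and flagged in the quality report, never zeroed, because the
online pipeline must emit continuous output.

The streaming applier buffers chunks to the same window grid, so chunked and
batch cleaning agree sample for sample.

### Reference, epochs, baseline, normalization

The common average reference is applied *after* ASR so that ASR sees
full-rank data and the rank reduction happens last. Epochs cover [0, 3) s
from task onset (cue offset). Baseline correction subtracts the per-trial,
per-channel mean over [−1, 0) s relative to *cue* onset — the last quiet
second before the cue appears; the pre-task segment is captured alongside
each epoch for this purpose. Finally epochs are z-scored per (session,
channel), pooling each session's trials; the statistics are stored for
reuse on online windows. Constant channels get an SD floor of 1e−12 and a
warning. Conventions throughout: seconds, 0-based sample indices, half-open
intervals [t0, t1).

Note one offline/online asymmetry: baseline correction needs cue knowledge
and is therefore offline-only. After the 4–36 Hz band-pass the per-window
mean is already near zero, so its absence online is immaterial; the
offline/online equivalence check compares the continuous-window path, which
uses identical operators on both sides.

## Features (`mibci.features`)

* **Morlet power.** Single-trial wavelet power with 2 cycles per frequency
  on a 2 Hz grid over 8–30 Hz (12 frequencies; the grid spacing is a
  repository choice, the range and cycle count are fixed), computed with
  `mne.time_frequency.tfr_array_morlet` and temporally decimated by 3
  ("keep every third output sample"). A 1 s window at 250 Hz yields 84 time
  points.
* **CSP.** One-vs-rest common spatial patterns: for each class the
  generalized eigenproblem `Σ_c w = λ (Σ_c + Σ_rest) w` is solved and the
  top and bottom eigenvectors kept — 2 per class, 6 filters for 3 classes.
  Covariances are plain averaged sample covariances (no regularization);
  features are `log(var(wᵀx))`. Because the common average reference leaves
  one exact null direction, the problem is solved in the span of the
  composite covariance (rank-truncated whitening); otherwise the "minimum
  variance" filter of every class would be the physically meaningless
  common-mode direction. Filters match a brute-force generalized
  eigensolver to 1e−8 on full-rank inputs.
* **Windowing and stacking.** Each 3 s epoch is cut into four 1 s windows
  (starts evenly spaced, i.e. stride 2/3 s). Morlet planes are flattened to
  channel×frequency feature channels (24×12 = 288) and the 6 CSP
  log-variances — computed per window, not per trial, since the classifier
  consumes per-window sequences — are tiled along the decimated time axis,
  giving a 294 × 84 tensor per window. Morlet-only and CSP-only ablation
  paths exist.
* **Splitting.** The stratified 80/20 split operates on *source trials*, not
  windows, so the four windows of a trial never straddle the
  train/test boundary (leakage guard); with a fixed windows-per-trial count
  the window-level fractions equal the trial-level ones up to whole-trial
  granularity. CSP is fitted on training windows only and the decomposition
  is serialized into the model checkpoint.

## Classifier (`mibci.model`)

### S4D layer

Each of the H hidden channels owns a diagonal complex state-space system
(A, B, C, D, dt) with N/2 stored conjugate-pair states. Zero-order hold
discretization gives `Ā = exp(dt·A)` and `B̄ = (Ā − 1)/A · B`; the
convolution kernel is

    K[l] = 2·Re( Σ_n C_n B̄_n Ā_n^l ),  l = 0 … L−1,

evaluated as a Vandermonde-structured product and applied by FFT convolution
(length 2L zero-padded, truncated to L — causal linear convolution).
Stability is enforced by reparameterization, `Re(A) = −exp(ρ)`, so |Ā| < 1
and the kernel envelope decays. Initialization follows S4D-Lin:
`A_n = −1/2 + iπn`, B = 1, C complex standard normal, dt log-uniform on
[1e−3, 1e−1] per channel. The kernel equals the impulse response of the
naive sequential recurrence to better than 1e−5 relative error; that
identity is the module's core oracle.

### Network

Input features are linearly projected to `hidden_dim`; then `num_layers`
pre-normalized blocks: LayerNorm → S4D convolution (forward and
time-reversed kernels, outputs concatenated — the bidirectional
realization) plus per-direction D·u skips → GELU → dropout (0.4) →
pointwise Conv1D → gated linear unit → residual. Temporal average pooling
and a linear head produce the 3-class logits. Defaults: hidden_dim 256,
3 layers, state_dim 64, bidirectional. The reduced benchmark configuration
(hidden 32, 1 layer) is what the synthetic recovery test trains.

The network and its training loop run on a small reverse-mode autodiff
engine over numpy arrays written for this package (`model/autograd.py`):
broadcasting elementwise ops, reductions, channel-wise linear maps, an FFT
convolution with analytic adjoint, and fused softmax cross-entropy. All
parameters are float64; gradients were verified against central finite
differences. Training uses Adam with two groups — SSM parameters (A, dt) at
1e−4, everything else at 1e−3, no weight decay — standard structured
state-space practice; these are repository defaults, as is the batch size
(32) and the early-stopping rule (validation accuracy, patience 10, best
parameters restored). Seeding covers initialization, batch order and
dropout masks, so training is reproducible on fixed hardware.

### Uncertainty

Monte-Carlo dropout: dropout stays active at inference and `n_passes`
stochastic forward passes (default 20) give the mean prediction, its
per-class SD, and the predictive entropy of the mean distribution — both
spread statistics are reported since neither is canonical. With dropout
rate 0 the spread is exactly zero.

### Baselines

SVM (RBF), random forest, AdaBoost, k-NN and MLP from scikit-learn, fitted
on flattened window features with standardization where the estimator needs
it; they share the split with the sequence model.

## Real-time runtime (`mibci.realtime`)

Stages (acquisition → preprocess → classify → transfer) are independent
units joined by bounded, order-preserving, non-blocking queues that drop the
*oldest* entry on overflow and count drops exactly. The default scheduler is
synchronous: it pumps the same queues in stage order, which is deterministic
— this is what makes the offline/online equivalence property testable on a
single CPU. A threaded mode runs the stages concurrently behind the
identical queue contract with a watchdog for stalled stages. Live transports
(LSL, network messaging) are out of scope; `replay()` turns any recording
into the chunk stream the contract expects (100 ms chunks by default,
optional real-time pacing).

The classify stage keeps a rolling buffer of cleaned samples and evaluates
the model on the trailing 1 s window every `hop_s` (default 0.1 s). Each
emitted control frame carries the four stage timestamps; summaries report
median/p95/p99 per stage using the nearest-rank percentile definition so
printed values are exactly reproducible.

The transfer function averages the last `buffer_len = 10` probability
vectors; the argmax class is emitted if its mean clears its threshold
(default 0.5 each), otherwise an explicit `neutral` token — never silence.
Ties break toward the lowest class index. Buffer length, thresholds and the
class→signal mapping are runtime-adjustable configuration; the defaults map
rest→neutral, left→x=−1, right→x=+1, and the mapping table supports all
five signals (x, y, a, b, neutral). Binary accumulators gain
`binary_fill_rate` on their class, decay otherwise, clamp to [0, 1], fire
for exactly one tick on reaching 1, then reset.

The Wolpaw information transfer rate is
`B = log₂N + P·log₂P + (1−P)·log₂((1−P)/(N−1))` bits per selection
(0·log 0 ≡ 0), scaled by 60/T selections per minute; it equals the mutual
information of the symmetric-confusion channel with uniform input, which the
tests verify against a brute-force evaluation.

## Training game (`mibci.dino`)

A QuickTime trial shows a cue for `window = 3 s`; each decoder decision tick
(0.1 s) adds `fill_rate = 1` bar unit on a match and subtracts
`decay_rate = 0.5` otherwise, clamped at zero; reaching `threshold = 5`
units triggers the jump (success) and ends the trial. The magnitudes are
repository choices — only the mechanic is externally fixed. Session reports
count per-class and overall success rates (strictly successes/trials) and
remaining health (start minus failures). A scripted decoder with adjustable
accuracy allows decoder-free evaluation; the bar process is a deterministic
function of the decision sequence, verified against an independent
Monte-Carlo simulation of the same Markov chain.

## Numerical choices and limitations

* Tolerances: chunked-vs-batch filtering agrees to 1e−9 (actually exact);
  offline/online window probabilities to 1e−5 (observed ~1e−13); CSP vs
  brute-force eigenvectors to 1e−8; S4D kernel vs recurrence to 1e−5.
* Degenerate inputs: zero-variance CSP projections are floored at
  log(1e−12) with a warning; constant channels get an SD floor in
  normalization; all-channel rejection, empty epoch sets, empty decision
  streams and empty latency logs raise.
* The S4D implementation is CPU/numpy; it is sized for the reduced
  benchmark configuration and small feature sets, not for GPU-scale
  training. The full 256×3 default trains, but slowly.
* ASR's finite-sample edge factor is a first-order correction; extremely
  short windows (<~10 samples per channel) would need a proper
  Marchenko–Pastur treatment.
* The simulator's ERD is a square gate on oscillation amplitude; real ERD
  has ramped onsets and rebound (ERS), which the ERDS-map code can display
  but the generator does not produce.
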