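# Methods

`dcafusion` predicts one of three lower-limb movements — standing up, sitting
down, walking — from two biosignal streams recorded under an
incomplete-asynchronous paradigm: motor-imagery (MI) EEG recorded alone in a
2 s window, and EEG + surface EMG recorded simultaneously only in the 1 s
pre-movement window that precedes execution.  This note documents the model,
the synthetic-data generator, the numerical choices, and what the shipped
experiments do and do not establish.

## The trial paradigm

A trial lasts 15 s: an instruction video with an audio prompt (0–3 s), a
fixation cue at 3.5 s, motor imagery from 5.5 s, a third prompt at 7.5 s,
movement execution at 8–10 s, and rest to 15 s.  The analysis windows are

* `mi_window` = [5.5, 7.5) s — MI EEG only (`x_eeg1`, C1 × T1),
* `sync_window` = [7.5, 8.5) s — simultaneous EEG (`x_eeg2`) and sEMG
  (`x_semg`, C2 × T2).

The sync window is informative for the sEMG side because muscle activation
leads movement by 0.5–1 s (the electromechanical delay plus reaction time),
so designated muscles are already active before execution begins.  At the
acquisition rates (EEG 1 kHz, sEMG 1.5 kHz) the epochs are exactly 2000,
1000 and 1500 samples with the half-open `[round(start*fs),
round(end*fs))` convention ("round" is round-half-up: banker's rounding
would make a 1 s epoch at 375 Hz come out one sample long).

Channel counts: 32 EEG electrodes and 10 leg muscles are recorded; one body
side (16 EEG channels + 5 muscles: rectus femoris, vastus lateralis,
tibialis anterior, biceps femoris, lateral gastrocnemius) is retained, the
configuration relevant to hemiplegia where only the affected side matters.
Some descriptions of this architecture give C1 = 14 instead of 16; both are
supported through configuration and 16 is the default.

## The model

Three encoders feed a co-attention fusion stage and a linear softmax head:

* **EEG encoder** (both EEG epochs, independent parameters for the two
  epoch lengths): temporal convolution (learns band-pass-like filters) →
  batch norm → depthwise spatial convolution across all electrodes → batch
  norm → ELU → average pool → dropout → separable convolution (depthwise
  temporal + pointwise) → batch norm → ELU → average pool → dropout.  This
  is the canonical compact convolutional recipe for MI EEG with default
  filter counts 8/2/16.  The temporal kernel length defaults to 64 samples
  and is configurable; we deliberately do not scale it with the sampling
  rate because patch extraction cost grows linearly with it on CPU.
* **sEMG encoder**: a single LSTM (hidden size 300 by default) applied
  channel by channel with shared weights — per-muscle temporal features —
  followed by two convolutions over the feature dimension and a depthwise
  convolution across muscles that extracts inter-muscle synergy features.
* **Dense co-attention (DCA) fusion** of the synchronized pair.  With
  sEMG-side state M (d × n_m) and EEG-side state E (d × n_e), one layer
  computes the bilinear affinity A = EᵀWM, row-softmax attention maps
  A_M = softmax(A) and A_E = softmax(Aᵀ), cross-attended features
  P_M = M·A_Mᵀ and P_E = E·A_Eᵀ, and residual fusion
  M' = ReLU(W_M[M; P_E] + b_M) + M (symmetrically for E').  Shapes are
  preserved, so layers stack; the default stack depth is N = 2, the
  smallest value that exercises stacking, and is configurable.  Encoder
  outputs whose size is a multiple of d are reshaped row-major to (d, n);
  otherwise a learned linear projection to d·n precedes the reshape.
  d defaults to 300, matching the LSTM dimension.
* **Head**: the MI-EEG features bypass fusion; the head is a linear map
  over `flatten(F_EEG1) ++ flatten(M_N) ++ flatten(E_N)` followed by
  softmax.  A weightless flatten-softmax cannot produce 3 class scores, so
  the linear layer is required by shape; prediction ties break to the
  lowest class index (argmax).

ELU is used inside the convolutional encoders and ReLU inside the DCA
layers; the two stages keep their own conventions.  Whether the two EEG
epochs should share encoder weights is an open design point; we default to
independent parameter sets since the inputs have different lengths.

**Training.** Adam (default moments), categorical cross-entropy, up to
`max_epochs` (1000 by default) with validation stopping: the returned
parameters are the snapshot with the lowest validation loss on a stratified
10% split of the training portion.  Batch size defaults to 16.  `patience`
optionally stops runs whose validation loss has not improved for a given
number of epochs.  All randomness (init, shuffling, dropout, splits)
derives from a single integer seed; two runs with the same seed produce
bit-identical parameters and histories.

The networks run on a small reverse-mode automatic-differentiation engine
over NumPy arrays (`dcafusion.autograd`, `dcafusion.nn`), written for this
package: convolutions are patch-extraction plus matrix products, so only a
dozen differentiable primitives are needed.  Everything is float64, which
makes the oracle comparisons in the test suite exact to round-off.  The
engine is deliberately minimal — no GPU, no graph optimization — and is fast
enough for the problem sizes shipped here.

## The synthetic-data generator

No public recordings exist for this paradigm, so the package generates its
own. The generator reproduces the statistical structure a decoder exploits,
not the biophysics:

* **EEG**: per-channel 1/f background (low-passed near 45 Hz) plus
  narrowband mu (8–12 Hz) and beta (18–26 Hz) rhythms on sensorimotor
  electrodes, with rhythm-to-background band power around 15 so that band
  power is the dominant in-band signal.  Motor imagery appears as
  event-related desynchronization: on class-designated channels the rhythm
  amplitude is scaled by √(1−erd_depth) from MI onset to the end of the
  sync window, so band power scales by 1−erd_depth.  Subject-level depth
  defaults to U(0.45, 0.65), a typical contralateral ERD magnitude.
* **sEMG**: 20–450 Hz baseline noise per muscle plus band-limited bursts on
  class-designated muscles from `onset_lead` (U(0.5, 1.0) s) before the
  movement marker to movement end, with burst gain U(3, 5) baseline
  standard deviations and a 0.1 s raised-cosine onset/offset ramp.
* **Subject variability**: log-normal channel gains (σ = 0.1), per-subject
  effect sizes, per-muscle gain jitter; all draws deterministic in
  (subject_id, seed).
* **Protocol**: 3 groups of 30 movements per subject (10 per class);
  walking/sitting randomized within the first 20 of each group, standing
  last (movements start from the complementary posture).  Rest periods are
  baseline only.  Trials are statistically independent; no inter-trial
  carry-over is modelled.

Class codings map classes to ERD channel sets and muscle sets.  The
`distinct` coding (default) gives every class its own signature in both
modalities.  The `partial` coding is a designed ambiguity for the fusion
benchmark: EEG carries no ERD for standing and identical ERD for sitting
and walking (EEG alone can only detect standing — ceiling 2/3 accuracy),
while sEMG activates the same quadriceps pattern for standing and sitting
and a distinct shank pattern for walking (sEMG alone can only detect
walking — ceiling 2/3).  Only the fused model can resolve all three
classes.

**What the simulator does not contain**: volume conduction and realistic
electrode covariance (no head model), ocular/motion artifacts,
non-stationary fatigue or adaptation effects, cross-talk between muscles,
and any within-class temporal structure beyond the band-power/burst model.
Passing results on this data demonstrate that the pipeline recovers the
class structure it is designed to recover — band-power modulation and
amplitude bursts — not that it would reach any particular accuracy on human
recordings.

## Preprocessing

sEMG: 50 Hz zero-phase IIR notch (Q = 12; ≥ 20 dB rejection at 50 Hz after
forward–backward application, < 1 dB at 30/80 Hz) followed by a 10–450 Hz
4th-order Butterworth band-pass (zero-phase).  EEG: 0.3–30 Hz band-pass.
Zero-phase filtering keeps the two modalities time-aligned.  Band edges are
clipped below Nyquist so the same chain runs on reduced-rate simulations;
the notch is skipped when the rate cannot represent 50 Hz.

Sliding windows (300 samples, step 100 — 200 ms at 1.5 kHz, 13 windows per
sync epoch) feed the handcrafted-feature baselines.  The deep model
consumes full epochs; whether windowed segments should also augment deep
training is left open and unimplemented.  Trailing samples short of a full
window are dropped.

## Baselines

Per sEMG channel per window: mean absolute value, waveform length, zero
crossings (deadband 0, configurable), 6th-order autoregressive coefficients
by the Yule–Walker/autocorrelation method (a constant window yields zeros),
and mean Welch PSD — 10 values, 650 per trial at full scale.  EEG: common
spatial patterns on the MI epoch, one-vs-rest for three classes, log-variance
features, n_components/2 filters from each end of the eigenvalue spectrum;
rank-deficient covariances are ridge-regularized with a warning.  Classical
classifiers (LDA, decision tree, naive Bayes, linear/RBF SVM, k-NN, a small
MLP) come from scikit-learn behind a uniform pipeline interface.

## Evaluation protocols

* **Within-subject**: per subject, a stratified 70/30 train/test split
  (per class, ⌊0.7·n⌋ to training, remainder to test), the 70% partitioned
  into 4 stratified cross-validation folds each validating once.  Reports
  include both the fold mean and the test accuracy of the
  best-validation-fold model, covering both common uses of the fold
  structure.
* **Cross-subject**: 5 random draws of 7 training / 3 test subjects; all
  trials follow their subject.  Splits are audited for leakage (train, val
  and test index sets must be pairwise disjoint in every fold).

Reports store raw per-fold and per-subject accuracies (CSV/JSON) so
downstream statistics (e.g. repeated-measures ANOVA) can be run by any
stats package; no significance testing is bundled.

## Problem sizes of the shipped experiments

The benchmark experiments simulate at EEG 64 Hz / sEMG 96 Hz (the same 2:3
rate ratio as the acquisition hardware) with the `tiny` network preset
(filters 4/2/8, LSTM hidden 16, d = 16): the multimodal-advantage
experiment uses 5 subjects × 120 trials = 600 trials with a stratified
70/30 holdout, 80 epochs for the fusion model and up to 40 for the
single-modality controls (batch 32, lr 1e-3, 15% validation split); the
label-shuffle control uses ~400 trials and a classical pipeline; the
modality-ordering check uses ~200 trials.  These sizes were chosen so the
whole suite runs on one CPU core; the full-scale defaults (1 kHz/1.5 kHz,
filters 8/2/16, LSTM 300, d = 300) are exercised for shape and arithmetic
correctness but not trained in the tests.

## Numerical choices and edge cases

* Softmax everywhere uses max-subtraction; attention rows sum to 1 within
  1e-6 by construction.
* Zero DCA weights are exactly the identity (ReLU(0) = 0 plus the residual
  path) — used as a regression anchor.
* Average pooling drops trailing samples; convolution "same" padding
  applies to the temporal axis only.
* The LSTM forget-gate bias initializes to 1.
* Per-channel standardization statistics are computed on the training set
  only and reused at prediction time.
* Checkpoints (.npz with a JSON config) round-trip to bit-identical
  predictions, including batch-norm running statistics.

## Known limitations

* The autograd engine keeps whole-graph activations in memory; batch sizes
  beyond a few hundred full-rate trials are impractical.
* Validation stopping on cross-entropy can select an early, underconfident
  snapshot when training is noisy; the shipped configurations (dropout
  0.25, lr 1e-3) were chosen so validation loss tracks accuracy.
* CSP assumes stationary covariance within epochs; the one-vs-rest
  reduction is one of several multi-class conventions.
* The simulator's independence assumptions make cross-subject
  generalization easier than on real data; cross-subject numbers here
  should not be compared with human-subject studies.
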