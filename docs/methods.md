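# Methods

## Problem and approach

`voxeldecode` asks whether two continuously performed task states — a
self-initiated (SI) and a visually guided (VG) finger-tapping run — can be
told apart from the BOLD time-series of a *single voxel*. Because a
continuous-state run has no block or event structure, there is no GLM
contrast to fit; the discriminative information, if any, sits in the temporal
dynamics of the series itself. The package implements a hybrid decoding
chain:

1. extract one voxel's series x(t) (T samples at interval TR);
2. project it onto a grid of frequency bands with the continuous wavelet
   transform, CWT(a, b) = |a|^(-1/2) ∫ x(t) ψ((t−b)/a) dt, using the
   Daubechies-2 mother wavelet ψ;
3. train a small 1D convolutional network per band on the coefficient rows
   (or on the raw series), scoring with the ROC AUC;
4. compare against a univariate baseline, wavelet-ALFF (the time-mean
   absolute coefficient per band), via paired t-tests and an AUC↔|T|
   calibration that converts a t-significance level into an AUC
   "efficiency" threshold.

## Band grid and scale conversion

The default grid covers 0.003–0.313 Hz in 32 steps of 0.01 Hz at TR = 2 s.
Scales follow the standard pseudo-frequency relation a = f_c / (f · TR) with
f_c the mother wavelet's dimensionless center frequency (2/3 for db2, the
dominant Fourier frequency of the sampled wavelet). At TR = 2 s the Nyquist
limit is 0.25 Hz, so the top seven bands are formally defined but aliased;
the grid builder computes them and emits a warning.

## CWT discretization and a real limitation

Coefficients are computed as the Riemann sum
|a|^(-1/2) · Σ_n x[n] ψ((n−b)/a) · TR with the series treated as zero
outside its support, one coefficient per native time shift b = 0…T−1 (no
cone-of-influence masking). ψ is evaluated by linear interpolation of a
dense cascade table (2^12 points per unit support). The fast path is an
exact convolution reformulation of that sum; a direct term-by-term oracle is
kept as test support and the two agree to ~1e-13 relative.

This point-sampled discretization has a consequence worth knowing: db2 has
compact support [0, 3], so a band at scale a has only ⌊3a⌋+1 kernel taps.
Above ~0.1 Hz (a < 3.3 samples) the kernels are 4–10 taps long, and the
empirical peak frequency response of such a short, coarsely sampled kernel
deviates from its nominal pseudo-frequency (the shortest kernels are
effectively broadband). A pure sinusoid therefore maximizes its band
response at the nominal nearest band only in the low and middle part of the
grid (verified at 0.003–0.033 Hz and 0.083 Hz); high-band labels should be
read as nominal scale labels, not as calibrated band-pass centers. Averaged
(rather than point-sampled) kernels would sharpen high-band selectivity but
would no longer compute the Riemann sum above; point sampling is kept as the
definition.

## Synthetic cohort generator

The generator emulates the target study design: `n_subjects` = 42 subjects ×
2 states, T = 230 samples, TR = 2 s. Each series is

* a 1/f^β Gaussian background (β = 1 by default), built in the frequency
  domain by scaling complex Gaussian spectra with f^(−β/2) and inverting —
  seedable with a controllable slope; unit SD by default;
* plus a sinusoid at the effect band (0.103 Hz by default) with random
  phase and amplitude `base_amplitude · subject_effect · (effect_ratio if
  SI else 1)`; `subject_effect = 1 + subject_sd·N(0,1)` (clipped at 0.1,
  SD 0.2 by default) is shared between a subject's two runs, giving
  between-subject amplitude variability;
* z-scored per series (configurable off), which makes all downstream inputs
  scale-free. Note that z-scoring rescales each state's total variance, so
  the analytic amplitude²→power law for the injected effect holds exactly
  only with z-scoring disabled.

Defaults (`base_amplitude` = 1, `noise_sd` = 1, `effect_ratio` = 2) put the
effect clearly above the noise floor at the effect band — a deliberate
"detectable effect" regime for power experiments, chosen because no
effect-size estimate exists for the real SI-vs-VG band differences. What the
generator does **not** model: hemodynamic response convolution (continuous
states have no event train), spatial structure, and structured physiological
noise (cardiac/respiratory aliasing). Passing tests on this generator show
the chain detects band-limited amplitude differences at realistic sample
sizes; they do not show that real SI/VG runs differ this way.

Per-(subject, state) random streams derive from (seed, subject, state), so
datasets are bitwise reproducible and growing the cohort never perturbs
existing subjects.

## The per-band CNN

Architecture (input: one band's coefficient row, length T, one channel):
three blocks of [conv1d(kernel 3, same padding) → batch-norm → LeakyReLU
(α = 0.3) → max-pool 2] with 32, 64, 128 filters, then flatten →
dense(128) + LeakyReLU + dropout 0.5 → dense(1) + sigmoid. For T = 230 the
pooling pyramid gives 230→115→57→28 and 490,497 trainable parameters. L1
(1e-5) penalizes all conv/dense kernels. Training: Adam (learning rate 5e-5;
the reference configuration also prints 1e-3 and both are exposed — 5e-5 is
the default), binary cross-entropy, batch size 2, 200 epochs by default.
Initialization: he-uniform conv kernels, LeCun-normal dense kernels (plain
normal with SD √(1/fan_in), not truncated), zero biases; batch-norm eps 1e-3,
momentum 0.99; Adam eps 1e-7. Per-sample z-scoring of feature vectors is on
by default. The engine is plain numpy (float32, convolutions as BLAS matrix
products over im2col windows), fully seeded and reproducible on one CPU.

After each epoch the model is scored on a monitor set and the best monitor
AUC over all epochs is kept; the whole run repeats 10 times from fresh
initializations and the mean AUC is reported. **The default monitor is the
test set**, mirroring the reference protocol ("best model on the test set").
This optimistically biases the reported AUC — at small monitor sizes the
max-over-epochs of a null model sits well above 0.5 (measured here: ~0.52
mean over 10 repetitions at the full design, but up to ~0.8 on 12-sample
monitor sets). An honest mode (`monitor="validation"`) selects the epoch on
a held-out quarter of the training data and reports the test AUC at that
epoch; every result records which monitor produced it. Splits are
class-stratified 75/25 at the sample level by default; a subject-level mode
keeps both runs of a subject on one side (sample-level splitting lets a
subject straddle the split, a known leakage channel — it is the default only
because it matches the reference protocol, and reports carry the mode).

## Wavelet-ALFF baseline and calibration

Wavelet-ALFF for band i is the time-mean |coefficient| of row i (an RMS
variant is available; the two are monotone-equivalent for ranking and AUC
purposes). As a decoder, a test sample's score is its own ALFF value,
sign-oriented by the training-set AUC (a rank statistic, so decoding AUC is
invariant under any strictly increasing transform of ALFF; orienting by
class means would break that invariance under nonlinear transforms). Paired
t-tests pair SI and VG by subject — the only pairing the design affords —
and default to the full sample (the test-split-only scope is exposed).

The calibration is an ordinary least-squares fit |T| = slope·AUC +
intercept across models; its inverse translates a t-threshold (e.g. |T| =
4.08, p < 0.0001 at 41 degrees of freedom) into an AUC efficiency cutoff.
The constant 0.61 shipped as the default threshold is the reference
analysis's value; the procedure — refit on your own models and invert —
is the method, and `auc_threshold_for_t` implements it.

## Comparison summaries

`summarize_comparison` pairs CNN and baseline results by (voxel, band),
counts models above the threshold per method, their overlap and union, and
the fraction of strict CNN wins within each ("ties favor neither").
`rank_models` ranks all 33 models of a voxel (32 bands + raw series, average
rank for ties, rank 1 best) and reports the mean rank of the raw-series
model across voxels. A full 25-voxel × 32-band dual-method design is exactly
800 pairs and 825 CNN models; a stub decoder mode exercises this bookkeeping
in seconds, since a real 825-model CNN run takes days on one CPU.

## Numerical and size choices

* Test-suite CNN property checks (power monotonicity, band specificity,
  null behaviour) run at reduced scale — 16–24 subjects, 64–128 samples,
  25–30 epochs, 1–3 repetitions, fixed seeds — sized so the full suite stays
  in the minutes range; the power experiment in the acceptance suite runs
  the full 42-subject, 230-sample, 60-epoch, 10-repetition condition.
* Band-specificity checks compare the effect band against **band 0** (the
  longest, most band-limited kernel). The nominally most distant band (31)
  is a 4-tap broadband kernel that still passes the effect frequency, so it
  is not a valid null comparator under this discretization.
* MNI→voxel lookup rounds to the nearest voxel, ties away from zero; no
  interpolation (the method is defined on single voxels). The packaged peak
  table stores coordinates exactly as published (unsigned); a per-axis sign
  override exists because left/posterior structures normally carry negative
  MNI x/y and the true signs are not recoverable from the published table.
* Series length is data-driven everywhere; 230 is the packaged default.
* Degenerate inputs fail loudly: zero-variance paired differences, single-
  class AUC inputs, constant calibration predictors and too-short CNN inputs
  all raise typed errors; an all-constant synthetic series returns zeros
  with a warning rather than dividing by zero.

## Known limitations

* High-band (> ~0.1 Hz) selectivity is nominal, not empirical (above).
* The default test-set monitor inflates AUCs by construction; use
  `monitor="validation"` for unbiased estimates.
* The synthetic effect is a stationary sinusoidal amplitude difference —
  the easiest case for both methods; real continuous-state differences are
  plausibly nonstationary and broader-band.
* The AUC↔|T| calibration is refit per dataset; its quality (R²) depends
  entirely on how homogeneous the model population is.
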