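# Methods

## Problem and model

The package estimates the UPDRS-III motor score — an integer clinical
rating of Parkinson's motor severity (0–108, higher is worse) — from two
triaxial gyroscopes (most-affected wrist and ankle, 64 Hz, deg/s) worn
during unscripted activities of daily living. Supervision is weak and
round-level: a neurologist scores each protocol *round*, and every 5 s
window inside the round inherits that score during training; at evaluation
time per-window estimates are averaged back to the round before comparison,
which smooths estimation outliers and matches the resolution at which the
label is defined.

The estimator is a dual-branch multichannel CNN-LSTM:

* **ConvR** (raw branch): 1D convolutions over the 320 × 6 window — block 1
  with 64 kernels of size 32, max-pool (pool 16, stride 4), dropout 0.1;
  block 2 with 128 kernels of size 8, dropout 0.2. With 'same' padding the
  pooled time axis is (320 − 16)/4 + 1 = 77 steps.
* **ConvS** (spectrogram branch): 2D convolutions over the 33 × 43 × 6 dB
  spectrogram image — block 1 with 64 5×5 kernels, 2×2 max-pool, dropout
  0.1; block 2 with 128 3×3 kernels, dropout 0.1 (spatial map 16 × 21).
* In pretext mode each branch ends in global pooling (average for ConvR,
  max for ConvS) giving a 128-vector; in regression mode the branches emit
  sequences (77 × 128; ConvS frequency-averaged to 21 × 128) consumed by
  one 128-unit LSTM each. The two last hidden states are concatenated and
  mapped dense(256, ReLU) → linear scalar. The output is unbounded;
  clipping to the clinical range is left to reporting.

Seven variants reuse these branch definitions — 1D/2D/multichannel CNN
(pooled features → dense head) and the corresponding CNN-LSTMs — forming
the supervised baseline ladder against which the self-supervised variant
is compared.

### Self-supervised pretext stage

Each unlabeled training window spawns three transformed copies:

* **rotation** — an independent uniform random 3D rotation of each
  sensor's axis triplet (axis uniform on the sphere, angle uniform in
  ±180°), emulating placement variability; per-timestep triplet norms are
  preserved exactly;
* **permutation** — the window cut into 4 equal contiguous segments,
  reordered by a random non-identity permutation (the value multiset is
  preserved);
* **time-warp** — resampling along a smooth monotone warp built from a
  cubic spline through 4 interior anchors perturbed with σ = 0.2 × window
  duration; endpoints fixed, non-monotone draws rejected.

Originals (pseudo-label 0,0,0) plus one singly-transformed copy per task
(one-hot labels) give 4 samples per window; spectrograms are always
recomputed from the transformed raw signal. One shared 128-unit task layer
per transformation sits on the concatenated pooled branch features with a
sigmoid output, trained with the weighted multi-task binary cross-entropy

L = Σ_t α_t · mean_b −[w₊ y log P_t + (1 − y) log(1 − P_t)],  α_t = 1.

The per-task positive weight w₊ = 3 compensates the 3:1 negative:positive
imbalance the one-transform-per-sample construction induces at each head.
(The loss is the standard negative log-likelihood; a sign/term variant
sometimes printed for this objective is unbounded below and cannot be the
minimized quantity.) Three heads are used; the untransformed originals act
as shared negatives rather than getting a fourth "is-original" head, which
would be redundant — its label is determined by the other three.

After pretraining, the convolutional weights of both branches are copied
into the regression network, **block 1 of each branch is frozen**, and
block 2 plus the freshly initialized LSTM/dense layers are fine-tuned with
the Huber loss (δ = 1), chosen for robustness to the outlying windows that
free-living recordings produce.

## Training procedure

Both stages use Adam (default 1e-4, 35 epochs, batch 32 — the published
recipe), early stopping on validation loss and plateau LR halving
(patience 5, floor 1e-6). The validation split (20 %) holds out whole
subjects inside the training fold so that no subject identity leaks across
the split; likewise all normalization statistics (per-channel z-score of
raw windows, per-channel min-max of dB spectrograms) are fitted on the
training fold only. Regression targets are z-scored on the training split
and the scaling inverted at prediction (`TrainConfig.target_standardize`),
so δ = 1 acts on a unit-variance scale; without this the Huber gradient
clips at ±1 and a desk-scale run cannot even traverse the ~25-point score
range in its few hundred optimizer steps.

Cross-validation is leave-one-subject-out by default (one fold per
subject, disjoint and exhaustive, audited); subject-grouped k-fold is
available for desk-scale work. Pooled metrics are computed over the
concatenated held-out rounds of all folds, and per-subject reports are
emitted alongside, since "average over subjects" and "pool rounds" differ
and both are informative. Pearson p-values use the two-sided t transform.

## Signal-processing choices

* The band edges 0.5/15 Hz are **3 dB** points; `firwin` places −6 dB at
  its cutoff, so the design cutoffs are adjusted by root finding until the
  realized response is −3 ± 0.01 dB at the printed edges. 513 taps at
  64 Hz give a ~0.4 Hz transition and > 50 dB stopband; coefficients are
  symmetrized to make linear phase exact. Filtering is forward–backward
  (zero phase) so that window contents are not delayed relative to
  annotations.
* The STFT uses a 1 s (64-sample) Kaiser window with β = 8 (≈ −58 dB
  sidelobes; β is a free choice) and 90 % overlap. The nominal hop
  64 × 0.1 = 6.4 samples is fractional; the overlap is rounded to 58
  samples (hop 6), the closest integer realization, giving
  ⌊(320 − 64)/6⌋ + 1 = 43 frames × 33 one-sided bins. Magnitudes are
  floored at −80 dB *before* the log, so an all-zero window maps to a
  constant floor image and amplitude scaling by c shifts every non-floored
  value by exactly 20 log₁₀ c dB. The full 0–32 Hz band is kept (the
  band-pass has already suppressed out-of-band energy); cropping is
  config-exposed.
* Windows are cut independently inside each round's non-excluded
  stretches; trailing partials are discarded and windows never straddle
  exclusion or round boundaries. Each window carries the dominant activity
  over its span.

## The synthetic cohort generator

The generator emulates the *structure* of a private two-site clinical
cohort so the pipeline is testable: a mixed cohort (≈ 5/8 structured
protocol A — four rounds of seven scripted ADLs of 15–60 s each, a
clinical-exam exclusion stretch at each round start; the rest continuous
protocol B — one unstructured session scored at start and end). Every
subject begins medication-OFF with an integer score drawn from 12–60;
ON-state rounds sit near a subject ON level (0.4–0.7 × OFF, clamped to
4–38); with probability 0.25 the final round reverts toward the OFF
baseline (wear-off).

Severity maps to signal through the two motor signatures the pipeline
targets:

* tremor: an amplitude-modulated sinusoid at a per-interval frequency from
  4–6 Hz with amplitude 25 · max(0, s − 15)/60 deg/s, twice as strong on
  wrist as ankle channels;
* bradykinesia: band-limited (0.5–3 Hz) noise movement with RMS
  30 · (1 − 0.6 s/60) deg/s, scaled per activity (resting 0.2×,
  ambulation 1.5×, others intermediate);
* additive white noise, σ = 2 deg/s.

The mapping is monotone but noisy, so recovery is scored by correlation.
A built-in *identifiability baseline* — linear regression of round-averaged
4–6 Hz band power on severity — reaches r > 0.7 on a 12-subject cohort,
guaranteeing the learning problem is solvable before any network runs.

What the generator does **not** emulate: biomechanically realistic gait,
dyskinesia, sensor drift/clipping, inter-subject kinematic idiosyncrasy,
or the rich cross-channel structure of real movement. Passing tests on
synthetic cohorts therefore demonstrates pipeline correctness and
end-to-end learnability, not clinical performance; the published clinical
correlation (computed on a private dataset) is out of reach by
construction.

## Desk-scale experiment sizes

Unit and acceptance experiments run width-reduced networks
(`NetworkConfig.reduced()`: 8/16 conv filters, 16-unit heads and LSTMs,
32-unit fusion) on cohorts with shortened rounds (60–90 s instead of
600 s), batch 16, learning rate 1e-3 and up to 30 epochs without premature
stopping — sizes chosen so a full cross-validated comparison of the
self-supervised and supervised variants runs on one CPU core in minutes.
The published full-width recipe remains the default configuration.

### Pretext transfer at reduced width: an honest negative result

At these desk-scale widths the self-supervised variant does **not** match
the supervised multichannel CNN-LSTM on synthetic cohorts: across master
seeds 1–3 the supervised variant reaches round-level r ≈ 0.80–0.89
(mean 0.83) while the transfer-and-freeze variant lands at r ≈ 0.58–0.73
(mean 0.66). A control
experiment attributes the gap: transferring *untrained* (random) branch
weights and freezing block 1 performs the same as transferring
pretext-trained weights. The deficit therefore comes from freezing an
8-filter first block — too small a fixed basis for the regression — not
from what pretraining put into those filters. Two corollaries follow.
First, the desk-scale recipe pretrains gently (5 epochs at 3e-4): on this
generator the pretext tasks are solvable through edge- and phase-sensitive
features that carry no tremor-amplitude information, so prolonged pretext
training actively rotates the frozen basis away from regression-relevant
directions (heavy pretraining measurably worsened downstream r). Second,
the synthetic comparison does not reproduce the published ordering (where
self-supervision helps at full width on clinical data) and should not be
expected to: frozen-basis sufficiency is a width-dependent property, and
the generator's simple two-feature structure makes the pretext tasks
nearly orthogonal to the target task. The suite asserts this comparison
anyway and the assertion documents the discrepancy when it fails.

## Numerical and engineering notes

* The NN engine computes in float32; convolutions are evaluated as sums of
  tap-shifted GEMMs, which profiling showed to be several times faster
  than an im2col buffer at these widths on one core. All layer gradients
  are verified against central finite differences in float64 during
  development and against float32 tolerances in the suite.
* Determinism: every stochastic component takes a seed (master seed fans
  out per stage as seed + stage ordinal); identical seeds give
  bit-identical cohorts, SSL datasets, and training histories in
  single-threaded numpy.
* Degenerate inputs: zero-variance targets flag the metric report rather
  than raising; rounds with zero windows are dropped from round averages;
  a single-subject corpus falls back to a window-level validation split;
  an identity permutation or non-monotone warp draw is rejected and
  resampled.
* Known limitations: no GPU path; LSTM backpropagation is a Python loop
  over 77 steps (adequate at these widths); the engine implements exactly
  the layers these architectures need, not a general framework.
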