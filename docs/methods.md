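# Methods

## Problem setting

Motor-imagery brain-computer interfaces decode imagined limb movement from
EEG. The usable signal is event-related desynchronisation/synchronisation
(ERD/ERS): imagining one hand attenuates mu (~8–13 Hz) and beta (~13–30 Hz)
band power over the contralateral sensorimotor cortex. Because the spatial
mixing, spectra and noise differ strongly between people, a classifier
trained on one group of subjects (the *source* domain) degrades on a new
subject (the *target*). This package implements zero-calibration transfer:
the target contributes only unlabeled trials, and the training objective
actively aligns the source and target feature distributions.

## Discrepancy statistics

All kernels are Gaussian RBF, `k(u, v) = exp(−‖u−v‖² / (2σ²))`. For a
source batch `{x_i^s}` (n_s trials) and target batch `{x_j^t}` (n_t
trials), stack the two sets, form the gram matrix `K_x`, and let
`W1 = v vᵀ` with `v = [1/n_s … 1/n_s, −1/n_t … −1/n_t]`. Then

* squared **MMD** (marginal alignment): `1ᵀ (K_x ∘ W1) 1` — the distance
  between the kernel mean embeddings of the two feature samples;
* squared **JDD** (joint alignment): `1ᵀ (K_x ∘ K_y ∘ W1) 1`, where `K_y`
  is the gram matrix of the per-trial softmax outputs — the
  Hilbert–Schmidt distance between tensor-product embeddings
  `φ(x) ⊗ ψ(y)` of the joint (feature, predicted-label) samples.

Both quadratic forms equal their explicit three-term double-sum expansions;
the test suite verifies this against literal-loop oracles on random
instances. The default estimator keeps the `i = j` terms (a V-statistic,
matching the quadratic form exactly); a diagonal-excluding U-statistic is
available via `unbiased=True`. With a constant label kernel JDD reduces to
MMD, which is also tested.

Bandwidths are resolved per evaluation by the median pairwise-distance
heuristic on the stacked batch, separately for the feature and label
kernels, with numeric overrides supported. Inside the training loss two
floors guard degenerate batches: 1e-3 for features and 0.1 for label
vectors (which live on the probability simplex, diameter √2, and are
near-coincident early in training when the softmax is still uniform).

## Network

The classifier is a six-stage convolutional network over epoched EEG
(trials × channels × time):

1. a bank of 32 temporal convolutions (length 16, same padding) applied to
   each channel, i.e. learned band filters; batch-norm, activation,
   dropout 0.2;
2. a depthwise spatial convolution — one channel-length filter per
   temporal map — the learned analogue of a CSP spatial filter (CSP picks
   `w` maximising the ratio of class-conditional variances of `wᵀX`);
   batch-norm, activation, dropout 0.2;
3. 16 × Conv2D (2×16), batch-norm, activation, maxpool (2, 4);
4. 4 × Conv2D (2×16), batch-norm, activation, maxpool (2, 8);
5. flatten — the feature tap for MMD/JDD and all diagnostics;
6. a dense softmax head over the N classes.

Output widths follow T, T/4, T/32 with non-overlapping floor-division
pooling, so the flatten width is `4·8·⌊⌊T/4⌋/8⌋` (= `4·8·T/32` when T is
divisible by 32). The default activation is the softplus `ln(1 + eˣ)`; the
conventional `relu` reading is available and is what the bundled benchmark
uses (see below). The spatial layer is depthwise so each of the 32 filters
is a single channel-weight vector whose absolute values can be read as a
scalp topography; a full-connectivity variant sits behind
`spatial_depthwise=False`. Initialisation is fan-in-scaled uniform from an
explicit seed; two builds with the same seed are bit-identical.

Batch-norm running statistics are updated by source batches only. During
training the target pass normalises with its own batch statistics;
evaluation uses the (source-derived) running statistics.

## Training protocol

The objective is

    L = CE(source) + γ_J · JDD²(source, target) + γ_M · MMD²(source, target)

computed per step from one labeled source batch and one unlabeled target
batch (both of size `ba`, default 32) flowing through the same frozen
weights; a single Adam update (default lr 1e-3; the benchmark uses 2e-3)
then backpropagates the composite gradient through both branches. With
`γ_J = γ_M = 0` the loop reproduces a plain supervised run bit-for-bit —
the target branch is never touched and the random streams are arranged so
source-side draws are identical.

Two scheduling safeguards matter at short training budgets, where the
alignment terms can otherwise collapse the features to a trivial common
embedding before any class structure exists (both discrepancies are zero
for constant features, which is a global attractor the cross-entropy
cannot escape once the representation has degenerated):

* the adaptation terms stay off until the epoch-mean source cross-entropy
  first drops below `ce_gate` (default 0.6 against the two-class chance
  level ln 2 ≈ 0.693);
* they then ramp linearly to their nominal weights over
  `gamma_warmup_frac` (default 0.25) of `max_epochs`.

Both discrepancies are still *measured* and traced every epoch from the
first step, so the JDD-vs-accuracy trace is complete. Setting
`ce_gate ≥ ln N` and `gamma_warmup_frac = 0` recovers the plain fixed-γ
objective.

γ_J and γ_M are selected over the grid {0.01, 0.1, 0.2, 0.5, 1, 2, 5, 10,
20} by 5-fold cross-validation on the source: the held-out fold enters
label-free as the target surrogate and held-out *source* accuracy is the
selection metric, since target labels do not exist by construction. The
joint 81-pair search is the default; a coordinate search (γ_J first with
γ_M = 0, then γ_M) is the budget option. Target labels never reach
training, γ selection, or stopping: `train_transfer` refuses a labeled
target set and takes monitoring labels, used only for the accuracy trace,
through a separate argument.

Leave-one-subject-out evaluation holds each subject out in turn as the
unlabeled target and reports one accuracy row per subject plus the
mean/variance aggregate.

## Synthetic data

`synth_eeg` generates two-class multi-subject trials: mu (10 Hz) and beta
(20 Hz) oscillators with random per-trial phase in two disjoint lateralised
channel groups, on a 1/f background (spectrally shaped white noise, scale
0.3) plus white sensor noise (σ = 0.5), all in unit-amplitude terms.
Imagining the left hand attenuates the *right*-group oscillators by
`erd_depth` (default 0.5) and vice versa — contralateral ERD. Cross-subject
shift has two knobs: each subject's sensor projection is
`orthonormalize(I + jitter · skew)` with a random skew-symmetric matrix
(scale stable, rotation growing with `subject_mixing_jitter`), and each
subject's oscillator frequencies are offset by up to `spectral_jitter_hz`
(default 1 Hz). Labels are emitted for every subject; hiding target labels
is the trainer's contract, not the generator's.

What this emulates: band-limited lateralised class structure, subject-
specific mixing, spectral variability, pink background. What it does not:
volume-conduction head geometry, artifacts (EOG/EMG), non-stationarity
within a session, class imbalance. Passing the synthetic benchmark
therefore demonstrates that the statistics and the training protocol work
as designed under controlled shift — not that real-EEG accuracies are
reproduced.

`shift_severity` summarises the shift between two subjects as the squared
MMD between per-trial log band-power vectors; it is zero for identical
trial sets, symmetric, and grows with the mixing jitter (tested over a
seed ensemble).

## The bundled benchmark

`deepjdd.benchmark` fixes one scaled-down study: 4 subjects, 16 channels,
100 Hz, 1.28 s epochs (T = 128), 30 trials per class per subject, mixing
jitter 0.4; subject 0 is the unlabeled target, subjects 1–3 the source;
18 training epochs, batch 32, Adam at 2e-3, float32 arithmetic, ReLU
activation; (γ_J, γ_M) = (1, 1) against (0, 0); five seeds. Epoch length
and trial counts were set from step-time measurements of the numpy
training loop so the five-seed replication completes in minutes on one
CPU. The ReLU reading is used here because the softplus form, being almost
linear for batch-normalised pre-activations, needs substantially more
steps to leave its initial plateau than this budget provides; the printed
softplus form remains the package default and trains fine at larger
budgets.

Per seed the benchmark reports: target accuracy with and without
adaptation, the Spearman correlation between epoch-wise JDD and monitored
target accuracy, the source-target discriminant-line angle in a 2-D
kernel-PCA embedding of the flatten features for both models, and whether
any layer-2 spatial filter peaks on a planted source channel.

## Diagnostics

* `kpca_embed_2d` projects features on the top-2 components of the
  doubly-centered RBF gram (scikit-learn KernelPCA with a precomputed
  kernel); component signs are fixed by the largest-magnitude-positive
  rule so embeddings are reproducible.
* `lda_line` is the two-class Fisher discriminant in the 2-D embedding:
  `w` solves `S_w w = m₁ − m₀` (ridge 1e-6 on singular scatter) and the
  line passes through the class-mean midpoint. It is cross-checked against
  a brute-force direction sweep of the Fisher criterion.
* `alignment_report` compares two models (typically with/without JDD) by
  the angle between their source and target discriminant lines and the
  cross-domain MMD of the embedded coordinates.
* `trace_correlation` is the Spearman rank correlation between epoch-wise
  JDD and monitored target accuracy; it returns NaN for constant series
  (undefined correlation).

## Preprocessing

The continuous-EEG chain is a causal Chebyshev type-2 bandpass (order 5,
20 dB stopband, stopband edges a fixed 25% transition band outside the
passband edges), cue-locked `[start, end)` epoch extraction with
round-half-up sample counts, polyphase anti-aliased downsampling
(`resample_poly` on the exact rational rate ratio), and per-epoch,
per-channel mean removal. Two canonical orderings are provided:
filter → epoch → demean for 250 Hz competition-style recordings (4–40 Hz)
and epoch → filter → downsample → demean for 512 Hz recordings (4–30 Hz,
to 100 Hz). With these settings a 0.5–5 s window at 100 Hz yields 450
samples and a 0.4–3 s window at 512 Hz yields 260 samples after
downsampling.

## Numerical choices and limitations

* Everything random is driven by explicit `numpy` generators; training is
  bit-reproducible for a fixed config on a fixed BLAS.
* float64 is the default; the benchmark trains in float32 for speed. The
  autodiff engine is gradient-checked against central finite differences.
* Squared pairwise distances inside the loss are clamped at zero before
  the kernel exponent (float cancellation can leave tiny negatives).
* Cross-entropy adds a 1e-30 floor inside the log to keep `0 · log 0` out
  of the off-class terms.
* Maxpool ties break toward the first maximal element (argmax), and
  pooling is non-overlapping with stride equal to the pool size.
* The gamma cross-validation at the full 81-pair grid is expensive at
  benchmark scale; the benchmark fixes (1, 1) vs (0, 0) instead of
  re-selecting per run.
* Known limitation: at very short budgets the adaptation gain depends on
  the cross-entropy gate engaging; if the source task itself is not
  learned, adapted and unadapted runs coincide at chance.
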