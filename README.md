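# deepjdd

Zero-calibration cross-subject decoding for motor-imagery EEG through
**joint distribution matching**: a deep CSP-like convolutional network
trained with a composite loss that aligns both the marginal and the joint
(feature, predicted-label) distributions of labeled *source* subjects and
an unlabeled *target* subject.

## Who this is for

BCI researchers who want a new subject to use a motor-imagery decoder
without a calibration session. Classifiers trained on other people degrade
on a new head: spatial mixing, mu/beta spectra and noise all shift between
subjects. Aligning only the marginal feature distribution P(x) is not
enough — the discriminative direction can still differ — so the training
objective also aligns the joint distribution P(x, y).

## The statistics

For flatten-layer features of a source batch (n_s trials) and a target
batch (n_t trials), stacked into one gram matrix K_x with RBF kernel
k(u, v) = exp(−‖u−v‖²/2σ²), and W1 = v vᵀ with
v = [1/n_s … 1/n_s, −1/n_t … −1/n_t]:

* squared maximum mean discrepancy (marginal alignment)

      MMD² = 1ᵀ (K_x ∘ W1) 1

* squared joint distribution discrepancy, with K_y the gram matrix of the
  per-trial softmax outputs (joint alignment)

      JDD² = 1ᵀ (K_x ∘ K_y ∘ W1) 1

and the training objective

      L = CE(source) + γ_J·JDD² + γ_M·MMD²

with γ selected from {0.01, 0.1, 0.2, 0.5, 1, 2, 5, 10, 20} by 5-fold
source cross-validation. Both statistics are verified against literal
double-sum oracles in the test suite; `jdd_sq_bruteforce` ships as the
independent reference implementation.

The network (`deepjdd.dcjnn`) is a six-stage CNN: a 32-filter temporal
convolution bank, a depthwise spatial filter layer (the learned CSP
analogue, exportable as channel topographies), two Conv2D/maxpool stages,
a flatten tap (where MMD/JDD attach), and a softmax head. The layers,
kernels and pooling follow the T → T/4 → T/32 width plan with flatten
width 4·8·T/32.

## Worked example

Train on three synthetic subjects, adapt to a fourth without its labels,
and compare against the same network trained without adaptation:

```python
import numpy as np
from deepjdd import (SyntheticConfig, generate_multisubject, LossWeights,
                     TrainConfig, NetworkSpec, train_transfer,
                     train_supervised, evaluate)

ds = generate_multisubject(SyntheticConfig(
    n_subjects=4, trials_per_class=30, n_channels=16, epoch_s=1.28,
    subject_mixing_jitter=0.4, seed=20260925))
target = ds.select(ds.subject_ids == 0)
source = ds.select(ds.subject_ids != 0)

cfg = TrainConfig(max_epochs=18, learning_rate=2e-3, seed=20260925,
                  dtype="float32",
                  network=NetworkSpec(n_classes=2, activation="relu"))

plain, _ = train_supervised(source, cfg)
adapted, trace = train_transfer(source, target.without_labels(),
                                LossWeights(gamma_J=1.0, gamma_M=1.0), cfg,
                                monitor_labels=target.labels)

print("unadapted target accuracy:", evaluate(plain, target)[0])
print("adapted target accuracy:  ", evaluate(adapted, target)[0])
```

which prints

```
unadapted target accuracy: 0.85
adapted target accuracy:   0.9833333333333333
```

(exact values are seed-dependent; the adapted model should be the better
one). `trace` holds per-epoch cross-entropy, MMD², JDD² and the monitored
target accuracy — the JDD series and the accuracy series rank-correlate
negatively, which is the signature of joint alignment doing its job.
`adapted.spatial_filter_weights()` returns the 32 learned channel-weight
vectors for topography inspection, and `deepjdd.diagnostics` adds the 2-D
kernel-PCA embedding with per-domain Fisher discriminant lines.

The same pipeline is scriptable from a shell: `deepjdd simulate`,
`deepjdd train`, `deepjdd evaluate`, `deepjdd loso`,
`deepjdd inspect-model`, `deepjdd diagnose`, `deepjdd preprocess` (see
`deepjdd --help`). Epoched data travel as a `.npy` array plus a `.json`
sidecar; continuous EDF/GDF recordings can be read through the optional
`mne` adapter and prepared with the Chebyshev-II bandpass / epoch /
downsample / demean chains in `deepjdd.preprocess`.

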