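"""The synthetic cross-subject transfer benchmark.

A scaled-down but complete version of the leave-one-subject-out study: four
synthetic subjects with lateralised mu/beta ERD structure and material
cross-subject mixing shift; one subject is held out as the unlabeled target
and the network is trained on the other three, once with joint-and-marginal
distribution matching (gamma_J = gamma_M = 1) and once without (0, 0).

Problem sizes (1.28 s epochs at 100 Hz, 30 trials per class per subject,
18 training epochs, float32 arithmetic, conventional-ReLU activation) were
fixed from step-time measurements of the numpy training loop so a full
five-seed replication completes in minutes on one CPU; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diagnostics import alignment_report, trace_correlation
from .dcjnn import NetworkSpec, forward_features
from .preprocess import remove_epoch_mean
from .synth_eeg import SyntheticConfig, generate_multisubject
from .trainer import (LossWeights, TrainConfig, TrainTrace, evaluate,
                      train_supervised, train_transfer)

__all__ = ["BENCHMARK_SYNTH", "benchmark_train_config", "run_transfer_once",
           "run_shift_benchmark", "SeedResult"]

#: study conditions of the synthetic shift benchmark (seed filled per run)
BENCHMARK_SYNTH = dict(
    n_subjects=4,
    trials_per_class=30,
    n_channels=16,
    srate_hz=100.0,
    epoch_s=1.28,
    erd_depth=0.5,
    subject_mixing_jitter=0.4,
    spectral_jitter_hz=1.0,
    noise_sigma=0.5,
)

ADAPTED = LossWeights(1.0, 1.0)
UNADAPTED = LossWeights(0.0, 0.0)


def benchmark_train_config(seed: int, max_epochs: int = 18) -> TrainConfig:
    """Training protocol of the benchmark (ba = 32, Adam, ReLU reading)."""
    return TrainConfig(
        batch_size=32,
        max_epochs=max_epochs,
        learning_rate=2e-3,
        seed=seed,
        dtype="float32",
        network=NetworkSpec(n_classes=2, activation="relu"),
    )


@dataclass
class SeedResult:
    """Everything one benchmark seed produces."""

    seed: int
    acc_adapted: float
    acc_unadapted: float
    trace_adapted: TrainTrace
    spearman_jdd_acc: float
    angle_with_jdd: float
    angle_without_jdd: float
    filter_top_channels: np.ndarray  # argmax channel of each spatial filter
    planted_channels: tuple[int, ...]

    @property
    def gain(self) -> float:
        return self.acc_adapted - self.acc_unadapted

    @property
    def filter_hit(self) -> bool:
        return bool(np.isin(self.filter_top_channels,
                            list(self.planted_channels)).any())


def run_transfer_once(seed: int, weights: LossWeights, *,
                      max_epochs: int = 18, monitor: bool = True):
    """One train/evaluate pass; returns (model, trace, target_acc, data)."""
    synth = SyntheticConfig(seed=seed, **BENCHMARK_SYNTH)
    ds = generate_multisubject(synth)
    target = ds.select(ds.subject_ids == 0)
    source = ds.select(ds.subject_ids != 0)
    config = benchmark_train_config(seed, max_epochs)
    if weights.adapting:
        model, trace = train_transfer(
            source, target.without_labels(), weights, config,
            monitor_labels=target.labels if monitor else None)
    else:
        model, trace = train_supervised(source, config)
    acc, _ = evaluate(model, target)
    return model, trace, acc, (source, target, synth)


def _feature_tap(model, epochs, n_max: int = 60) -> np.ndarray:
    data = remove_epoch_mean(epochs).data[:n_max]
    return forward_features(model, data)


def run_seed(seed: int, max_epochs: int = 18) -> SeedResult:
    """Adapted-vs-unadapted comparison plus all diagnostics for one seed."""
    m_ad, tr_ad, acc_ad, (source, target, synth) = run_transfer_once(
        seed, ADAPTED, max_epochs=max_epochs)
    m_un, _, acc_un, _ = run_transfer_once(seed, UNADAPTED,
                                           max_epochs=max_epochs)
    rho = trace_correlation(tr_ad)
    n = 60
    angles = {}
    for name, model in (("with_jdd", m_ad), ("without_jdd", m_un)):
        try:
            rep = alignment_report(
                {name: _feature_tap(model, source, n)},
                {name: _feature_tap(model, target, n)},
                source.labels[:n], target.labels[:n])
            angles[name] = rep["models"][name]["angle_deg"]
        except ValueError:
            # a degenerate (e.g. collapsed) feature set has no embedding;
            # score it as the worst possible disagreement
            angles[name] = 90.0
    filters = m_ad.spatial_filter_weights()
    return SeedResult(
        seed=seed,
        acc_adapted=acc_ad,
        acc_unadapted=acc_un,
        trace_adapted=tr_ad,
        spearman_jdd_acc=rho,
        angle_with_jdd=angles["with_jdd"],
        angle_without_jdd=angles["without_jdd"],
        filter_top_channels=filters.argmax(axis=1),
        planted_channels=tuple(synth.left_group) + tuple(synth.right_group),
    )


def run_shift_benchmark(base_seed: int, n_seeds: int = 5,
                        max_epochs: int = 18) -> list[SeedResult]:
    """The full five-seed replication used by tests and the results script."""
    return [run_seed(base_seed + k, max_epochs=max_epochs)
            for k in range(n_seeds)]
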