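"""Synthetic multi-subject two-class motor-imagery EEG.

The generator emulates the band-power physiology that motor-imagery decoders
exploit: mu (~10 Hz) and beta (~20 Hz) oscillators live in two lateralised
channel groups, and imagining one hand desynchronises (attenuates) the
oscillation over the *contralateral* group (ERD).  Cross-subject
distribution shift is produced by giving each subject its own near-orthogonal
spatial mixing perturbation and its own oscillator frequency offsets, on top
of 1/f background activity and white sensor noise.

Every draw is a pure function of the config seed, so all downstream tests
and benchmarks are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .discrepancy import FeatureBatch, KernelConfig, mmd_sq
from .preprocess import EpochSet

__all__ = ["SyntheticConfig", "generate_multisubject", "shift_severity",
           "log_bandpower_features"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the two-class ERD/ERS simulation.

    Amplitudes are in arbitrary microvolt-like units: oscillators have unit
    amplitude before ERD attenuation, the 1/f background is scaled by
    ``background_scale`` and the white sensor noise by ``noise_sigma``.
    """

    n_subjects: int = 4
    trials_per_class: int = 60
    n_channels: int = 16
    srate_hz: float = 100.0
    epoch_s: float = 2.6
    mu_hz: float = 10.0
    beta_hz: float = 20.0
    erd_depth: float = 0.5
    left_group: tuple[int, ...] = (2, 3, 4)
    right_group: tuple[int, ...] = (11, 12, 13)
    subject_mixing_jitter: float = 0.4
    spectral_jitter_hz: float = 1.0
    noise_sigma: float = 0.5
    background_scale: float = 0.3
    beta_rel_amp: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        # tolerate JSON-style lists for the channel groups
        object.__setattr__(self, "left_group", tuple(self.left_group))
        object.__setattr__(self, "right_group", tuple(self.right_group))
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError("erd_depth must lie in [0, 1]")
        lg, rg = set(self.left_group), set(self.right_group)
        if lg & rg:
            raise ValueError("left_group and right_group must be disjoint")
        if any(i < 0 or i >= self.n_channels for i in lg | rg):
            raise ValueError("group channel index out of range")
        if self.subject_mixing_jitter < 0 or self.spectral_jitter_hz < 0 \
                or self.noise_sigma < 0:
            raise ValueError("jitters and noise must be nonnegative")

    @property
    def n_times(self) -> int:
        return int(round(self.epoch_s * self.srate_hz))


def _subject_mixing(n_ch: int, jitter: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Identity + jitter * (random skew-symmetric), re-orthonormalised.

    Keeps per-channel scale stable across subjects while rotating the
    source-to-sensor projection by an amount controlled by ``jitter``.
    """
    if jitter == 0.0:
        # consume the same number of draws so subject streams stay aligned
        rng.standard_normal((n_ch, n_ch))
        return np.eye(n_ch)
    A = rng.standard_normal((n_ch, n_ch))
    skew = (A - A.T) / 2.0
    q, r = np.linalg.qr(np.eye(n_ch) + jitter * skew)
    return q * np.sign(np.diag(r))  # fix QR sign ambiguity


def _pink_noise(shape: tuple[int, ...], n_times: int,
                rng: np.random.Generator) -> np.ndarray:
    """Approximate 1/f background via spectral shaping of white noise."""
    white = rng.standard_normal(shape + (n_times,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_times)
    scale = np.where(freqs > 0, 1.0 / np.sqrt(np.maximum(freqs, 1e-12)), 0.0)
    shaped = np.fft.irfft(spec * scale, n=n_times, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    return shaped / np.where(sd > 0, sd, 1.0)


def generate_multisubject(config: SyntheticConfig) -> EpochSet:
    """Draw the full multi-subject EpochSet described by ``config``.

    Class 0 ("left hand") attenuates the oscillators over ``right_group``
    by ``erd_depth`` (contralateral ERD) and vice versa.  Labels are emitted
    for every subject; hiding target labels is the trainer's job.
    """
    rng = np.random.default_rng(config.seed)
    n_t = config.n_times
    t = np.arange(n_t) / config.srate_hz
    n_trials_subj = 2 * config.trials_per_class
    all_data, all_labels, all_subjects = [], [], []
    for subj in range(config.n_subjects):
        mix = _subject_mixing(config.n_channels, config.subject_mixing_jitter,
                              rng)
        dmu = rng.uniform(-1, 1) * config.spectral_jitter_hz
        dbeta = rng.uniform(-1, 1) * config.spectral_jitter_hz
        labels = np.repeat([0, 1], config.trials_per_class)
        rng.shuffle(labels)
        latent = np.zeros((n_trials_subj, config.n_channels, n_t))
        if config.background_scale > 0:
            latent += config.background_scale * _pink_noise(
                (n_trials_subj, config.n_channels), n_t, rng)
        for k, label in enumerate(labels):
            # contralateral attenuation: class 0 = left hand -> right group
            gains = {config.left_group: 1.0, config.right_group: 1.0}
            if label == 0:
                gains[config.right_group] = 1.0 - config.erd_depth
            else:
                gains[config.left_group] = 1.0 - config.erd_depth
            for group, gain in gains.items():
                for ch in group:
                    ph_mu, ph_beta = rng.uniform(0, 2 * np.pi, size=2)
                    osc = gain * (
                        np.sin(2 * np.pi * (config.mu_hz + dmu) * t + ph_mu)
                        + config.beta_rel_amp
                        * np.sin(2 * np.pi * (config.beta_hz + dbeta) * t
                                 + ph_beta))
                    latent[k, ch] += osc
        sensors = np.einsum("ij,kjt->kit", mix, latent)
        if config.noise_sigma > 0:
            sensors = sensors + config.noise_sigma * rng.standard_normal(
                sensors.shape)
        all_data.append(sensors)
        all_labels.append(labels)
        all_subjects.append(np.full(n_trials_subj, subj))
    return EpochSet(
        data=np.concatenate(all_data),
        labels=np.concatenate(all_labels),
        subject_ids=np.concatenate(all_subjects),
        srate_hz=config.srate_hz,
        channel_names=[f"ch{i}" for i in range(config.n_channels)],
        class_names=["left", "right"],
    )


def log_bandpower_features(epochs: EpochSet,
                           bands: tuple[tuple[float, float], ...] = ((8, 13),
                                                                     (13, 30)),
                           ) -> np.ndarray:
    """Per-trial log band power (Welch) per channel per band, (trials x d)."""
    nper = min(epochs.n_times, int(epochs.srate_hz))
    freqs, psd = signal.welch(epochs.data, fs=epochs.srate_hz,
                              nperseg=nper, axis=-1)
    feats = []
    for lo, hi in bands:
        m = (freqs >= lo) & (freqs < hi)
        feats.append(np.log(psd[:, :, m].mean(axis=-1) + 1e-12))
    return np.concatenate(feats, axis=1)


def shift_severity(epochs: EpochSet, subj_a, subj_b) -> float:
    """Symmetric scalar summary of the distribution shift between subjects.

    Squared MMD (median-bandwidth RBF) between the two subjects' per-trial
    log band-power feature vectors; 0 when the trial sets are identical.
    """
    mask_a = epochs.subject_ids == subj_a
    mask_b = epochs.subject_ids == subj_b
    if not mask_a.any() or not mask_b.any():
        raise ValueError("unknown subject id")
    feats = log_bandpower_features(epochs)
    return mmd_sq(FeatureBatch(feats[mask_a]), FeatureBatch(feats[mask_b]),
                  KernelConfig())
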