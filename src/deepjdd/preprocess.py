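"""Continuous-to-epoch EEG preparation.

Causal Chebyshev type-2 bandpass, cue-locked epoch extraction, polyphase
downsampling with anti-aliasing, and per-epoch mean removal — the chain a
motor-imagery pipeline applies between raw recordings and the network input.

Two canonical chains are provided:

* ``graza_chain``: bandpass (4-40 Hz) -> epoch -> demean, for 250 Hz
  competition-style recordings;
* ``giga_chain``: epoch -> bandpass (4-30 Hz) -> downsample (100 Hz) ->
  demean, for 512 Hz recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "EpochSet",
    "FilterSpec",
    "bandpass",
    "extract_epoch",
    "downsample",
    "remove_epoch_mean",
    "graza_chain",
    "giga_chain",
]

# fraction of each passband edge used as the transition band to the
# corresponding Chebyshev-II stopband edge
TRANSITION_RATIO = 0.25


@dataclass
class EpochSet:
    """Labeled/unlabeled epoched EEG for one or more subjects.

    ``data`` is trials x channels x time (microvolts); ``labels`` may be
    None for an unlabeled target set.
    """

    data: np.ndarray
    labels: np.ndarray | None
    subject_ids: np.ndarray
    srate_hz: float
    channel_names: list[str]
    class_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")
        if self.srate_hz <= 0:
            raise ValueError("srate_hz must be positive")
        n_trials, n_ch, _ = self.data.shape
        self.subject_ids = np.asarray(self.subject_ids)
        if self.subject_ids.shape[0] != n_trials:
            raise ValueError("subject_ids length != trial count")
        if len(self.channel_names) != n_ch:
            raise ValueError("channel_names length != channel count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape[0] != n_trials:
                raise ValueError("labels length != trial count")
            if self.class_names and self.labels.size and \
                    self.labels.max() >= len(self.class_names):
                raise ValueError("label index exceeds class_names")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Trial subset preserving label/subject alignment."""
        return EpochSet(
            data=self.data[mask],
            labels=None if self.labels is None else self.labels[mask],
            subject_ids=self.subject_ids[mask],
            srate_hz=self.srate_hz,
            channel_names=list(self.channel_names),
            class_names=list(self.class_names),
        )

    def without_labels(self) -> "EpochSet":
        return EpochSet(data=self.data, labels=None,
                        subject_ids=self.subject_ids, srate_hz=self.srate_hz,
                        channel_names=list(self.channel_names),
                        class_names=list(self.class_names))


@dataclass(frozen=True)
class FilterSpec:
    """Chebyshev type-2 bandpass specification."""

    low_hz: float
    high_hz: float
    order: int = 5
    stopband_atten_db: float = 20.0
    causal: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def design_sos(self, srate_hz: float) -> np.ndarray:
        """Second-order sections for the given sampling rate.

        Stopband edges sit a fixed 25% transition band outside the passband
        edges (clipped below Nyquist).
        """
        nyq = srate_hz / 2.0
        if self.high_hz >= nyq:
            raise ValueError(
                f"high_hz={self.high_hz} must be below Nyquist {nyq}")
        ws_low = self.low_hz * (1.0 - TRANSITION_RATIO)
        ws_high = min(self.high_hz * (1.0 + TRANSITION_RATIO), nyq * 0.99)
        return signal.cheby2(self.order, self.stopband_atten_db,
                             [ws_low, ws_high], btype="bandpass",
                             fs=srate_hz, output="sos")


def bandpass(data: np.ndarray, srate_hz: float, spec: FilterSpec) -> np.ndarray:
    """Bandpass a channels x time array; causal by default.

    With ``causal=True`` the output at time t depends only on inputs up to t
    (scipy ``sosfilt``); ``causal=False`` gives a zero-phase forward-backward
    pass.
    """
    data = np.asarray(data, dtype=np.float64)
    sos = spec.design_sos(srate_hz)
    if spec.causal:
        return signal.sosfilt(sos, data, axis=-1)
    return signal.sosfiltfilt(sos, data, axis=-1)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def extract_epoch(continuous: np.ndarray, events: list[int] | np.ndarray,
                  window_s: tuple[float, float], srate_hz: float, *,
                  labels: np.ndarray | None = None,
                  subject_id=0,
                  channel_names: list[str] | None = None,
                  class_names: list[str] | None = None) -> EpochSet:
    """Cut cue-locked [start, end) windows out of a continuous recording.

    The epoch length is ``round_half_up((end - start) * srate)`` samples;
    trial order follows event order.  Events whose windows do not fit are
    reported together in one error.
    """
    continuous = np.asarray(continuous, dtype=np.float64)
    if continuous.ndim != 2:
        raise ValueError("continuous must be channels x time")
    start_s, end_s = window_s
    if end_s <= start_s:
        raise ValueError("window end must exceed start")
    n_samples = _round_half_up((end_s - start_s) * srate_hz)
    offset = _round_half_up(start_s * srate_hz)
    n_time = continuous.shape[1]
    bad = [int(e) for e in events
           if e + offset < 0 or e + offset + n_samples > n_time]
    if bad:
        raise ValueError(f"epoch window exceeds recording for events {bad}")
    trials = np.stack([continuous[:, e + offset:e + offset + n_samples]
                       for e in events]) if len(events) else \
        np.empty((0, continuous.shape[0], n_samples))
    n_ch = continuous.shape[0]
    return EpochSet(
        data=trials,
        labels=labels,
        subject_ids=np.full(len(events), subject_id),
        srate_hz=srate_hz,
        channel_names=channel_names or [f"ch{i}" for i in range(n_ch)],
        class_names=class_names or [],
    )


def downsample(epochs: EpochSet, target_hz: float) -> EpochSet:
    """Polyphase anti-aliased resampling of every epoch to ``target_hz``."""
    if target_hz > epochs.srate_hz:
        raise ValueError("upsampling is not supported")
    if target_hz == epochs.srate_hz:
        return replace(epochs)
    frac = Fraction(target_hz / epochs.srate_hz).limit_denominator(1000)
    out = signal.resample_poly(epochs.data, frac.numerator, frac.denominator,
                               axis=-1)
    return EpochSet(data=out, labels=epochs.labels,
                    subject_ids=epochs.subject_ids, srate_hz=float(target_hz),
                    channel_names=list(epochs.channel_names),
                    class_names=list(epochs.class_names))


def remove_epoch_mean(epochs: EpochSet) -> EpochSet:
    """Subtract each trial's per-channel time mean (idempotent)."""
    data = epochs.data - epochs.data.mean(axis=-1, keepdims=True)
    return EpochSet(data=data, labels=epochs.labels,
                    subject_ids=epochs.subject_ids, srate_hz=epochs.srate_hz,
                    channel_names=list(epochs.channel_names),
                    class_names=list(epochs.class_names))


def graza_chain(continuous: np.ndarray, events, srate_hz: float, *,
                window_s: tuple[float, float] = (0.5, 5.0),
                spec: FilterSpec | None = None, **epoch_kwargs) -> EpochSet:
    """Competition-style chain: bandpass 4-40 Hz -> epoch -> demean."""
    spec = spec or FilterSpec(low_hz=4.0, high_hz=40.0)
    filtered = bandpass(continuous, srate_hz, spec)
    epochs = extract_epoch(filtered, events, window_s, srate_hz,
                           **epoch_kwargs)
    return remove_epoch_mean(epochs)


def giga_chain(continuous: np.ndarray, events, srate_hz: float, *,
               window_s: tuple[float, float] = (0.4, 3.0),
               spec: FilterSpec | None = None,
               target_hz: float = 100.0, **epoch_kwargs) -> EpochSet:
    """512 Hz-style chain: epoch -> bandpass 4-30 Hz -> downsample -> demean."""
    spec = spec or FilterSpec(low_hz=4.0, high_hz=30.0)
    epochs = extract_epoch(continuous, events, window_s, srate_hz,
                           **epoch_kwargs)
    filtered = EpochSet(data=bandpass(epochs.data, srate_hz, spec),
                        labels=epochs.labels, subject_ids=epochs.subject_ids,
                        srate_hz=srate_hz,
                        channel_names=list(epochs.channel_names),
                        class_names=list(epochs.class_names))
    return remove_epoch_mean(downsample(filtered, target_hz))
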