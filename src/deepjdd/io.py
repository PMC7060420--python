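"""EpochSet container IO and the optional continuous-EEG adapter.

The on-disk container is one ``<stem>.npy`` array (trials x channels x time,
little-endian float32) plus a ``<stem>.json`` sidecar holding labels,
subject ids, sampling rate, channel/class names and free-form provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import EpochSet

__all__ = ["save_epochset", "load_epochset", "read_continuous"]


def save_epochset(epochs: EpochSet, stem: str | Path, *,
                  provenance: dict | None = None) -> tuple[Path, Path]:
    """Write ``<stem>.npy`` + ``<stem>.json``; returns both paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    npy = stem.with_suffix(".npy")
    meta = stem.with_suffix(".json")
    np.save(npy, epochs.data.astype("<f4"))
    sidecar = {
        "labels": None if epochs.labels is None else epochs.labels.tolist(),
        "subject_ids": np.asarray(epochs.subject_ids).tolist(),
        "srate_hz": float(epochs.srate_hz),
        "channel_names": list(epochs.channel_names),
        "class_names": list(epochs.class_names),
        "provenance": provenance or {},
    }
    meta.write_text(json.dumps(sidecar))
    return npy, meta


def load_epochset(stem: str | Path) -> EpochSet:
    """Read a container written by :func:`save_epochset`."""
    stem = Path(stem)
    data = np.load(stem.with_suffix(".npy")).astype(np.float64)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    labels = sidecar["labels"]
    return EpochSet(
        data=data,
        labels=None if labels is None else np.asarray(labels, dtype=int),
        subject_ids=np.asarray(sidecar["subject_ids"]),
        srate_hz=sidecar["srate_hz"],
        channel_names=sidecar["channel_names"],
        class_names=sidecar["class_names"],
    )


def read_continuous(path: str | Path) -> tuple[np.ndarray, float, list[str],
                                               list[int]]:
    """EDF/GDF adapter: continuous array, rate, channel names, event samples.

    Requires the optional ``mne`` dependency (``pip install deepjdd[edf]``).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF/GDF requires the optional 'mne' dependency") from exc
    path = Path(path)
    reader = {".edf": mne.io.read_raw_edf, ".gdf": mne.io.read_raw_gdf}.get(
        path.suffix.lower())
    if reader is None:
        raise ValueError(f"unsupported continuous format {path.suffix!r}")
    raw = reader(path, preload=True, verbose="error")
    events, _ = mne.events_from_annotations(raw, verbose="error")
    return (raw.get_data() * 1e6, float(raw.info["sfreq"]),
            list(raw.ch_names), [int(e[0]) for e in events])
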