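"""On-disk dataset container: one numeric array per subject + JSON sidecar.

Raw epochs for subject ``S`` are stored as ``sub-S_epochs.npy`` with
shape (epochs, 3, samples) next to a ``sub-S.json`` sidecar holding the
labels, sampling rate, stimulation frequencies, subject id and the
generating seed. Feature epochs use the same pattern with the frequency
axis in the sidecar. An optional EDF reader (requires ``mne``) maps
recordings with O1/Oz/O2 channels into epochs via sidecar-declared
event onsets.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import FeatureEpoch
from .simulate import CHANNEL_LABELS, RawEpoch

__all__ = [
    "save_raw_dataset",
    "load_raw_dataset",
    "save_feature_dataset",
    "load_feature_dataset",
    "read_edf_epochs",
]


def save_raw_dataset(
    directory, epochs: Sequence[RawEpoch], subject_id: str | None = None,
    stim_freqs: Sequence[float] | None = None, seed: int | None = None,
) -> Path:
    """Write one subject's raw epochs and sidecar; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not epochs:
        raise ValueError("no epochs to save")
    sid = subject_id or epochs[0].subject_id or "S1"
    stack = np.stack([e.samples for e in epochs])
    np.save(directory / f"sub-{sid}_epochs.npy", stack)
    sidecar = {
        "subject_id": sid,
        "labels": [int(e.class_index) for e in epochs],
        "sampling_rate": epochs[0].sampling_rate,
        "channel_labels": list(epochs[0].channel_labels),
        "stim_freqs": list(stim_freqs) if stim_freqs is not None else None,
        "seed": seed,
        "kind": "raw",
    }
    path = directory / f"sub-{sid}.json"
    path.write_text(json.dumps(sidecar, indent=2))
    return path


def load_raw_dataset(directory, subject_id: str | None = None) -> list[RawEpoch]:
    """Load raw epochs; if ``subject_id`` is None, load every subject found."""
    directory = Path(directory)
    if subject_id is not None:
        sidecars = [directory / f"sub-{subject_id}.json"]
    else:
        sidecars = sorted(directory.glob("sub-*.json"))
    epochs: list[RawEpoch] = []
    for sc in sidecars:
        meta = json.loads(sc.read_text())
        if meta.get("kind") != "raw":
            continue
        stack = np.load(directory / f"sub-{meta['subject_id']}_epochs.npy")
        for samples, label in zip(stack, meta["labels"]):
            epochs.append(
                RawEpoch(
                    samples=samples,
                    class_index=int(label),
                    sampling_rate=meta["sampling_rate"],
                    subject_id=meta["subject_id"],
                    channel_labels=tuple(meta["channel_labels"]),
                )
            )
    if not epochs:
        raise FileNotFoundError(f"no raw dataset found in {directory}")
    return epochs


def save_feature_dataset(
    directory, features: Sequence[FeatureEpoch], subject_id: str | None = None
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not features:
        raise ValueError("no features to save")
    sid = subject_id or features[0].subject_id or "S1"
    stack = np.stack([f.values for f in features])
    np.save(directory / f"sub-{sid}_features.npy", stack)
    sidecar = {
        "subject_id": sid,
        "labels": [int(f.class_index) for f in features],
        "freq_axis": features[0].freq_axis.tolist(),
        "normalized": bool(features[0].normalized),
        "kind": "features",
    }
    path = directory / f"sub-{sid}_features.json"
    path.write_text(json.dumps(sidecar, indent=2))
    return path


def load_feature_dataset(directory, subject_id: str | None = None) -> list[FeatureEpoch]:
    directory = Path(directory)
    if subject_id is not None:
        sidecars = [directory / f"sub-{subject_id}_features.json"]
    else:
        sidecars = sorted(directory.glob("sub-*_features.json"))
    feats: list[FeatureEpoch] = []
    for sc in sidecars:
        meta = json.loads(sc.read_text())
        stack = np.load(directory / f"sub-{meta['subject_id']}_features.npy")
        axis = np.asarray(meta["freq_axis"])
        for values, label in zip(stack, meta["labels"]):
            feats.append(
                FeatureEpoch(
                    values=values,
                    freq_axis=axis,
                    class_index=int(label),
                    subject_id=meta["subject_id"],
                    normalized=meta["normalized"],
                )
            )
    if not feats:
        raise FileNotFoundError(f"no feature dataset found in {directory}")
    return feats


def read_edf_epochs(
    edf_path, onsets_s: Sequence[float], labels: Sequence[int],
    duration_s: float = 4.0, subject_id: str = "",
) -> list[RawEpoch]:
    """Cut O1/Oz/O2 epochs out of an EDF recording (requires ``mne``).

    ``onsets_s``/``labels`` declare the stimulation events (typically read
    from a JSON sidecar next to the EDF file).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF ingestion needs the optional 'mne' dependency (pip install cossvep[edf])"
        ) from exc
    if len(onsets_s) != len(labels):
        raise ValueError("onsets_s and labels must have equal length")
    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    picks = []
    lower = {name.lower(): name for name in raw.ch_names}
    for wanted in CHANNEL_LABELS:
        if wanted.lower() not in lower:
            raise ValueError(f"EDF file lacks required channel {wanted}; has {raw.ch_names}")
        picks.append(lower[wanted.lower()])
    data = raw.get_data(picks=picks)
    fs = float(raw.info["sfreq"])
    n_keep = int(round(duration_s * fs))
    epochs = []
    for onset, label in zip(onsets_s, labels):
        start = int(round(onset * fs))
        if start < 0 or start + n_keep > data.shape[1]:
            raise ValueError(f"epoch at onset {onset}s exceeds the recording")
        epochs.append(
            RawEpoch(
                samples=data[:, start : start + n_keep] * 1e6,  # volts -> microvolts
                class_index=int(label),
                sampling_rate=fs,
                subject_id=subject_id,
            )
        )
    return epochs
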