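"""Multi-subject feature fusion for collaborative SSVEP decoding.

Three fusion operators combine the normalized spectral features that K
subjects produced while fixating the same flickering target:

* **parallel** — stack along the channel axis, (3K) x B: more "leads",
  consumed by a deeper channel-collapsing network;
* **serial** — concatenate along the frequency axis, 3 x (K*B): same
  channel count, wider spectrum, consumed by a wider-filter network;
* **average** — element-wise mean, 3 x B: shape-preserving, consumed by
  the unmodified single-person network.

Fusion consumes *normalized* features; parallel/serial merely rearrange
values while averaging is the only operator that creates new ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .features import FeatureEpoch
from .simulate import RawEpoch

__all__ = [
    "FusedFeature",
    "fuse_parallel",
    "fuse_serial",
    "fuse_average",
    "fuse",
    "align_group_trials",
]

FusionKind = Literal["parallel", "serial", "average"]


@dataclass
class FusedFeature:
    """Fusion result with provenance: kind, member order and class label."""

    values: np.ndarray
    kind: FusionKind
    member_ids: tuple[str, ...]
    class_index: int
    bins_per_subject: int

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def _check_members(features: Sequence[FeatureEpoch]) -> None:
    if len(features) == 0:
        raise ValueError("need at least one member feature")
    first = features[0]
    for i, f in enumerate(features):
        if not f.normalized:
            raise ValueError(f"member {i} is not normalized; fusion expects [0,1] features")
        if f.values.shape != first.values.shape:
            raise ValueError(
                f"member {i} has shape {f.values.shape}, expected {first.values.shape}"
            )
        if f.class_index != first.class_index:
            raise ValueError(
                f"member {i} carries class {f.class_index} but member 0 carries "
                f"{first.class_index}; fused members must share the stimulus"
            )


def fuse_parallel(features: Sequence[FeatureEpoch]) -> FusedFeature:
    """Channel-axis stacking in member order: (S1-O1, S1-Oz, S1-O2, S2-O1, ...)."""
    _check_members(features)
    return FusedFeature(
        values=np.vstack([f.values for f in features]),
        kind="parallel",
        member_ids=tuple(f.subject_id for f in features),
        class_index=features[0].class_index,
        bins_per_subject=features[0].n_bins,
    )


def fuse_serial(features: Sequence[FeatureEpoch]) -> FusedFeature:
    """Frequency-axis concatenation per channel: row c = [S1 ch c | S2 ch c | ...]."""
    _check_members(features)
    return FusedFeature(
        values=np.hstack([f.values for f in features]),
        kind="serial",
        member_ids=tuple(f.subject_id for f in features),
        class_index=features[0].class_index,
        bins_per_subject=features[0].n_bins,
    )


def fuse_average(features: Sequence[FeatureEpoch]) -> FusedFeature:
    """Element-wise mean; shape-compatible with the single-person network."""
    _check_members(features)
    return FusedFeature(
        values=np.mean([f.values for f in features], axis=0),
        kind="average",
        member_ids=tuple(f.subject_id for f in features),
        class_index=features[0].class_index,
        bins_per_subject=features[0].n_bins,
    )


_FUSERS = {"parallel": fuse_parallel, "serial": fuse_serial, "average": fuse_average}


def fuse(features: Sequence[FeatureEpoch], kind: FusionKind) -> FusedFeature:
    """Dispatch to the named fusion operator."""
    try:
        return _FUSERS[kind](features)
    except KeyError:
        raise ValueError(f"unknown fusion kind {kind!r}; expected one of {sorted(_FUSERS)}")


def align_group_trials(
    group: Sequence[Sequence[RawEpoch | FeatureEpoch]],
) -> list[tuple]:
    """Zip per-subject trial lists into per-trial tuples, enforcing alignment.

    Trial k of every subject must carry the same class label (the shared
    collaborative stimulus); any mismatch raises with the offending index.
    """
    if len(group) == 0:
        raise ValueError("group is empty")
    lengths = {len(subject) for subject in group}
    if len(lengths) != 1:
        raise ValueError(f"subjects have differing trial counts: {sorted(lengths)}")
    tuples = []
    for k, trials in enumerate(zip(*group)):
        labels = {t.class_index for t in trials}
        if len(labels) != 1:
            raise ValueError(
                f"label mismatch at trial {k}: subjects report classes {sorted(labels)}"
            )
        tuples.append(tuple(trials))
    return tuples
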