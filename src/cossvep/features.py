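"""Band-limited magnitude-spectrum features for SSVEP classification.

The feature pipeline is: zero-phase 4th-order Butterworth band-pass
(5-40 Hz) -> onset-anchored analysis window -> per-channel magnitude of
the real-input FFT (no taper, no zero padding) -> retain the 6-32 Hz
band (half-open, [low, high)) -> per-channel min-max normalization.

For a 3 s window at 256 Hz the frequency resolution is 1/3 Hz and the
[6, 32) band retains exactly 78 bins, giving the canonical 3 x 78 input
matrix of the single-person classifier. Shorter windows coarsen the
resolution and shrink the bin count; downstream networks are built per
bin count rather than hard-coded at 78.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .simulate import RawEpoch

__all__ = [
    "FeatureEpoch",
    "BandSpec",
    "bandpass_filter",
    "extract_window",
    "magnitude_spectrum",
    "select_band",
    "minmax_normalize",
    "featurize",
]


@dataclass
class FeatureEpoch:
    """Channels x frequency-bins magnitude spectrum of one trial."""

    values: np.ndarray
    freq_axis: np.ndarray
    class_index: int
    subject_id: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.freq_axis = np.asarray(self.freq_axis, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D channels x bins matrix")
        if self.values.shape[1] != self.freq_axis.shape[0]:
            raise ValueError(
                f"freq_axis length {self.freq_axis.shape[0]} does not match "
                f"{self.values.shape[1]} feature columns"
            )
        if np.any(np.diff(self.freq_axis) <= 0):
            raise ValueError("freq_axis must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class BandSpec:
    """Half-open frequency band [low, high) in Hz used for bin selection."""

    low: float = 6.0
    high: float = 32.0

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"need 0 < low < high, got [{self.low}, {self.high})")


def bandpass_filter(
    epoch: RawEpoch, low: float = 5.0, high: float = 40.0, order: int = 4
) -> RawEpoch:
    """Zero-phase Butterworth band-pass, applied independently per channel.

    Forward-backward (``sosfiltfilt``) application squares the magnitude
    response and cancels phase distortion; the effective attenuation is
    therefore twice the single-pass Butterworth roll-off in dB.
    """
    nyquist = epoch.sampling_rate / 2.0
    if not low < high < nyquist:
        raise ValueError(
            f"cutoffs must satisfy {low} < {high} < Nyquist ({nyquist} Hz)"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=epoch.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, epoch.samples, axis=1)
    return RawEpoch(
        samples=filtered,
        class_index=epoch.class_index,
        sampling_rate=epoch.sampling_rate,
        subject_id=epoch.subject_id,
        channel_labels=epoch.channel_labels,
    )


def extract_window(epoch: RawEpoch, window_s: float) -> RawEpoch:
    """Keep the first ``round(window_s * fs)`` samples, anchored at onset."""
    n_keep = int(round(window_s * epoch.sampling_rate))
    if not 0 < n_keep <= epoch.n_samples:
        raise ValueError(
            f"window of {window_s} s ({n_keep} samples) invalid for an epoch "
            f"of {epoch.n_samples} samples"
        )
    return RawEpoch(
        samples=epoch.samples[:, :n_keep].copy(),
        class_index=epoch.class_index,
        sampling_rate=epoch.sampling_rate,
        subject_id=epoch.subject_id,
        channel_labels=epoch.channel_labels,
    )


def magnitude_spectrum(epoch: RawEpoch) -> FeatureEpoch:
    """Per-channel |FFT| of the raw window: no taper, no zero padding.

    The frequency axis runs 0..Nyquist in steps of 1/window_s Hz
    (``n//2 + 1`` bins for n samples).
    """
    if epoch.n_samples == 0:
        raise ValueError("epoch has no samples")
    mags = np.abs(np.fft.rfft(epoch.samples, axis=1))
    freqs = np.fft.rfftfreq(epoch.n_samples, d=1.0 / epoch.sampling_rate)
    return FeatureEpoch(
        values=mags,
        freq_axis=freqs,
        class_index=epoch.class_index,
        subject_id=epoch.subject_id,
        normalized=False,
    )


def select_band(features: FeatureEpoch, band: BandSpec | None = None) -> FeatureEpoch:
    """Retain frequency bins with band.low <= f < band.high."""
    if band is None:
        band = BandSpec()
    # tiny tolerance so bin frequencies that are exact in rational arithmetic
    # (e.g. 18/3 = 6.0) are kept/excluded as intended despite float rounding
    eps = 1e-9
    mask = (features.freq_axis >= band.low - eps) & (features.freq_axis < band.high - eps)
    if not np.any(mask):
        raise ValueError(
            f"band [{band.low}, {band.high}) selects no bins from axis "
            f"[{features.freq_axis[0]}, {features.freq_axis[-1]}]"
        )
    return FeatureEpoch(
        values=features.values[:, mask],
        freq_axis=features.freq_axis[mask],
        class_index=features.class_index,
        subject_id=features.subject_id,
        normalized=features.normalized,
    )


def minmax_normalize(features: FeatureEpoch) -> FeatureEpoch:
    """Per-channel min-max rescaling to [0, 1]; constant channels map to zeros."""
    if features.normalized:
        raise ValueError("features are already normalized")
    lo = features.values.min(axis=1, keepdims=True)
    hi = features.values.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(features.values)
    nonconstant = span[:, 0] > 0
    out[nonconstant] = (features.values[nonconstant] - lo[nonconstant]) / span[nonconstant]
    return FeatureEpoch(
        values=out,
        freq_axis=features.freq_axis.copy(),
        class_index=features.class_index,
        subject_id=features.subject_id,
        normalized=True,
    )


def featurize(
    epoch: RawEpoch,
    window_s: float | None = None,
    band: BandSpec | None = None,
    filter_low: float = 5.0,
    filter_high: float = 40.0,
    normalize: bool = True,
) -> FeatureEpoch:
    """Full pipeline: filter -> window -> spectrum -> band -> normalize."""
    out = bandpass_filter(epoch, filter_low, filter_high)
    if window_s is not None:
        out = extract_window(out, window_s)
    feats = select_band(magnitude_spectrum(out), band)
    return minmax_normalize(feats) if normalize else feats
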