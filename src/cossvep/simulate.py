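"""Synthetic SSVEP EEG generation.

Emulates the statistical structure of occipital steady-state visually
evoked potentials recorded during a four-target flicker paradigm: each
trial is a narrowband response at the stimulation frequency and its
harmonics (amplitude decaying as 1/h, phase advancing as h*phi), riding
on broadband background noise that mixes pink (1/f) and white components.
Three correlated occipital channels (O1, Oz, O2) are modelled through
relative channel gains; inter-subject variability enters through an
amplitude scale, an SNR offset and a response-latency jitter.

Everything is deterministic given a seed, so every downstream stage of
the pipeline is testable without external recordings.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimulationConfig",
    "SubjectProfile",
    "RawEpoch",
    "simulate_trial",
    "simulate_subject_dataset",
    "simulate_group",
    "estimate_snr_db",
]

#: Occipital electrode montage used throughout the package.
CHANNEL_LABELS = ("O1", "Oz", "O2")

#: Flicker frequencies of the four stimulation targets, Hz.
DEFAULT_STIM_FREQS = (8.6, 10.0, 12.0, 15.0)

#: Flicker phases of the four targets, radians.
DEFAULT_STIM_PHASES = (1.35 * np.pi, 0.35 * np.pi, 0.9 * np.pi, 0.35 * np.pi)


@dataclass(frozen=True)
class SimulationConfig:
    """Stimulation paradigm and noise model parameters.

    Parameters
    ----------
    stim_freqs
        Flicker frequency of each stimulation target, Hz.
    stim_phases
        Flicker phase of each target, radians. Must align with ``stim_freqs``.
    sampling_rate
        Sampling frequency, Hz.
    trial_duration
        Stimulation length per trial, seconds.
    n_harmonics
        Number of harmonics of the flicker frequency present in the response.
    snr_db
        Ratio of total SSVEP power to total noise power per channel, dB.
    pink_fraction
        Proportion of noise power carried by the 1/f (pink) component;
        the remainder is white Gaussian.
    channel_gains
        Relative response gain of (O1, Oz, O2); Oz is typically dominant.
    seed
        Base seed for profile generation helpers.
    """

    stim_freqs: tuple[float, ...] = DEFAULT_STIM_FREQS
    stim_phases: tuple[float, ...] = DEFAULT_STIM_PHASES
    sampling_rate: float = 256.0
    trial_duration: float = 4.0
    n_harmonics: int = 3
    snr_db: float = -6.0
    pink_fraction: float = 0.7
    channel_gains: tuple[float, ...] = (0.9, 1.0, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stim_freqs) != len(self.stim_phases):
            raise ValueError(
                "stim_freqs and stim_phases must have equal length, got "
                f"{len(self.stim_freqs)} and {len(self.stim_phases)}"
            )
        max_harmonic = max(self.stim_freqs) * self.n_harmonics
        if self.sampling_rate <= 2.0 * max_harmonic:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz cannot represent the "
                f"highest harmonic at {max_harmonic} Hz (Nyquist violation)"
            )
        if any(g <= 0 for g in self.channel_gains) or len(self.channel_gains) != 3:
            raise ValueError("channel_gains must be three positive values")
        if not 0.0 <= self.pink_fraction <= 1.0:
            raise ValueError("pink_fraction must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.stim_freqs)

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.trial_duration))


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject response characteristics.

    ``amplitude_scale`` multiplies the evoked response, ``snr_offset_db``
    shifts the configured SNR, and ``latency_jitter`` delays the response
    relative to stimulus onset (seconds).
    """

    subject_id: str = "S1"
    amplitude_scale: float = 1.0
    snr_offset_db: float = 0.0
    latency_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")


@dataclass
class RawEpoch:
    """A single time-domain EEG trial: 3 occipital channels x samples."""

    samples: np.ndarray
    class_index: int
    sampling_rate: float
    subject_id: str = ""
    channel_labels: tuple[str, ...] = CHANNEL_LABELS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"samples must be {len(self.channel_labels)} x T, got shape "
                f"{self.samples.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-power 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0  # no DC drift
    pink = np.fft.irfft(spec * scale, n)
    return pink / np.std(pink)


def _ssvep_waveform(
    config: SimulationConfig, class_index: int, profile: SubjectProfile
) -> np.ndarray:
    """Noise-free evoked response, one row per channel."""
    f0 = config.stim_freqs[class_index]
    phi = config.stim_phases[class_index]
    t = np.arange(config.n_samples) / config.sampling_rate
    wave = np.zeros(config.n_samples)
    for h in range(1, config.n_harmonics + 1):
        wave += (profile.amplitude_scale / h) * np.sin(
            2.0 * np.pi * h * f0 * (t - profile.latency_jitter) + h * phi
        )
    gains = np.asarray(config.channel_gains)
    return gains[:, None] * wave[None, :]


def simulate_trial(
    config: SimulationConfig,
    class_index: int,
    profile: SubjectProfile | None = None,
    seed: int = 0,
) -> RawEpoch:
    """Simulate one SSVEP trial for one subject.

    The evoked waveform sums ``n_harmonics`` harmonics of the stimulation
    frequency with 1/h amplitude decay and h*phi phase progression, scaled
    per channel. Independent pink+white noise is added per channel, scaled
    so that evoked power / noise power matches the effective SNR
    (``config.snr_db + profile.snr_offset_db``).
    """
    if profile is None:
        profile = SubjectProfile()
    if not 0 <= class_index < config.n_classes:
        raise ValueError(
            f"class_index {class_index} out of range for {config.n_classes} targets"
        )
    rng = np.random.default_rng(seed)
    signal = _ssvep_waveform(config, class_index, profile)

    snr_db = config.snr_db + profile.snr_offset_db
    snr_linear = 10.0 ** (snr_db / 10.0)
    n = config.n_samples
    noise = np.empty_like(signal)
    for c in range(signal.shape[0]):
        pink = _pink_noise(rng, n)
        white = rng.standard_normal(n)
        white = white / np.std(white)
        mix = np.sqrt(config.pink_fraction) * pink + np.sqrt(
            1.0 - config.pink_fraction
        ) * white
        mix = mix / np.std(mix)
        signal_power = np.mean(signal[c] ** 2)
        noise[c] = mix * np.sqrt(signal_power / snr_linear)
    return RawEpoch(
        samples=signal + noise,
        class_index=class_index,
        sampling_rate=config.sampling_rate,
        subject_id=profile.subject_id,
    )


def simulate_subject_dataset(
    config: SimulationConfig,
    profile: SubjectProfile | None = None,
    trials_per_class: int = 12,
    seed: int = 0,
) -> list[RawEpoch]:
    """Simulate a balanced, shuffled session of trials for one subject.

    The class schedule (trial order) depends only on ``seed`` and the
    paradigm, never on the profile, so subjects simulated with the same
    seed share an identical label sequence.
    """
    if trials_per_class < 1:
        raise ValueError("trials_per_class must be >= 1")
    if profile is None:
        profile = SubjectProfile()
    schedule_rng = np.random.default_rng(seed)
    schedule = np.repeat(np.arange(config.n_classes), trials_per_class)
    schedule_rng.shuffle(schedule)
    epochs = []
    for k, cls in enumerate(schedule):
        subject_key = zlib.crc32(profile.subject_id.encode("utf-8"))
        trial_seed = np.random.SeedSequence(
            entropy=seed, spawn_key=(subject_key, k)
        ).generate_state(1)[0]
        epochs.append(simulate_trial(config, int(cls), profile, seed=int(trial_seed)))
    return epochs


def _draw_profiles(
    config: SimulationConfig, n_subjects: int, seed: int
) -> list[SubjectProfile]:
    """Deterministically draw subject profiles spanning realistic variability."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xC0,)))
    profiles = []
    for i in range(n_subjects):
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1}",
                amplitude_scale=float(np.exp(rng.normal(0.0, 0.2))),
                snr_offset_db=float(rng.normal(0.0, 2.0)),
                latency_jitter=float(rng.uniform(0.0, 0.03)),
            )
        )
    return profiles


def simulate_group(
    config: SimulationConfig,
    n_subjects: int,
    trials_per_class: int = 12,
    seed: int = 0,
) -> list[list[RawEpoch]]:
    """Simulate several subjects fixating the same stimulus sequence.

    All subjects share one class schedule (the collaborative-gaze
    assumption: everyone looks at the same flickering target on every
    trial), while per-subject profiles and noise differ.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    profiles = _draw_profiles(config, n_subjects, seed)
    return [
        simulate_subject_dataset(config, prof, trials_per_class, seed=seed)
        for prof in profiles
    ]


def estimate_snr_db(
    epoch: RawEpoch, config: SimulationConfig, class_index: int | None = None
) -> float:
    """Estimate evoked-to-background SNR of one epoch, in dB.

    Least-squares projection of each channel onto the sine/cosine pair at
    every harmonic of the stimulation frequency; the fitted component is
    the evoked-signal estimate and the residual the noise estimate. The
    regressor subspace has 2*n_harmonics dimensions out of ~1000 samples,
    so the noise bias absorbed into the fit is negligible.
    """
    cls = epoch.class_index if class_index is None else class_index
    f0 = config.stim_freqs[cls]
    t = np.arange(epoch.n_samples) / epoch.sampling_rate
    cols = []
    for h in range(1, config.n_harmonics + 1):
        cols.append(np.sin(2 * np.pi * h * f0 * t))
        cols.append(np.cos(2 * np.pi * h * f0 * t))
    design = np.column_stack(cols)
    snrs = []
    for ch in epoch.samples:
        coef, *_ = np.linalg.lstsq(design, ch, rcond=None)
        fit = design @ coef
        resid = ch - fit
        snrs.append(np.mean(fit**2) / np.mean(resid**2))
    return float(10.0 * np.log10(np.mean(snrs)))
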