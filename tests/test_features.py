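"""Feature pipeline: filter response, windowing, FFT geometry, normalization."""

import numpy as np
import pytest
from scipy import signal as sps

from cossvep import (
    BandSpec,
    FeatureEpoch,
    RawEpoch,
    bandpass_filter,
    extract_window,
    featurize,
    magnitude_spectrum,
    minmax_normalize,
    select_band,
    simulate_trial,
)


def sinusoid_epoch(freq, fs=256.0, duration=4.0, amp=1.0):
    t = np.arange(int(round(fs * duration))) / fs
    wave = amp * np.sin(2 * np.pi * freq * t)
    return RawEpoch(samples=np.tile(wave, (3, 1)), class_index=0, sampling_rate=fs)


class TestBandpass:
    # oracle: the designed 4th-order Butterworth's own magnitude response,
    # squared because the filter is applied forward and backward
    def sos_gain_db(self, freq, fs=256.0, low=5.0, high=40.0, order=4):
        sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
        return 2 * 20 * np.log10(np.abs(h[0]))

    def test_passband_10hz_rms_attenuation_below_1pct(self):
        assert self.sos_gain_db(10.0) > 20 * np.log10(0.99)  # design check
        epoch = sinusoid_epoch(10.0)
        out = bandpass_filter(epoch)
        mid = slice(128, -128)  # ignore filtfilt edge transients
        rms_in = np.sqrt(np.mean(epoch.samples[:, mid] ** 2))
        rms_out = np.sqrt(np.mean(out.samples[:, mid] ** 2))
        assert rms_out / rms_in > 0.99

    def test_stopband_50hz_attenuated_at_least_20db(self):
        assert self.sos_gain_db(50.0) < -20  # design check
        epoch = sinusoid_epoch(50.0)
        out = bandpass_filter(epoch)
        mid = slice(128, -128)
        rms_in = np.sqrt(np.mean(epoch.samples[:, mid] ** 2))
        rms_out = np.sqrt(np.mean(out.samples[:, mid] ** 2))
        assert 20 * np.log10(rms_out / rms_in) < -20

    def test_dc_maps_to_zero(self):
        epoch = RawEpoch(np.full((3, 1024), 5.0), 0, 256.0)
        out = bandpass_filter(epoch)
        assert np.max(np.abs(out.samples)) < 0.05

    def test_cutoff_at_nyquist_raises(self):
        epoch = sinusoid_epoch(10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(epoch, low=5.0, high=128.0)

    def test_shape_preserved(self):
        epoch = sinusoid_epoch(10.0)
        assert bandpass_filter(epoch).samples.shape == epoch.samples.shape


class TestWindow:
    @pytest.mark.parametrize(
        "window_s,expected", [(3.0, 768), (4.0, 1024), (1.6, 410), (2.0, 512)]
    )
    def test_sample_counts(self, window_s, expected):
        epoch = sinusoid_epoch(10.0)
        assert extract_window(epoch, window_s).samples.shape == (3, expected)

    def test_full_window_is_identity(self):
        epoch = sinusoid_epoch(10.0)
        out = extract_window(epoch, 4.0)
        assert np.array_equal(out.samples, epoch.samples)

    def test_window_anchored_at_onset(self):
        epoch = sinusoid_epoch(10.0)
        out = extract_window(epoch, 2.0)
        assert np.array_equal(out.samples, epoch.samples[:, :512])

    def test_overlong_window_raises(self):
        with pytest.raises(ValueError, match="window"):
            extract_window(sinusoid_epoch(10.0), 5.0)


class TestSpectrum:
    def test_zero_signal_gives_zero_spectrum(self):
        epoch = RawEpoch(np.zeros((3, 768)), 0, 256.0)
        assert np.all(magnitude_spectrum(epoch).values == 0)

    def test_12hz_sinusoid_peaks_at_bin_36_of_3s_axis(self):
        epoch = extract_window(sinusoid_epoch(12.0), 3.0)
        feats = magnitude_spectrum(epoch)
        assert feats.values.shape[1] == 385  # 768 // 2 + 1 rfft bins
        assert np.argmax(feats.values[0]) == 36  # 12 Hz / (1/3 Hz)
        assert feats.freq_axis[36] == pytest.approx(12.0)

    def test_parseval_no_taper_no_padding(self):
        rng = np.random.default_rng(0)
        epoch = RawEpoch(rng.standard_normal((3, 768)), 0, 256.0)
        feats = magnitude_spectrum(epoch)
        n = 768
        for c in range(3):
            mags = feats.values[c] ** 2
            # rfft halves the two-sided spectrum except DC and Nyquist
            spectral = (2 * mags.sum() - mags[0] - mags[-1]) / n
            assert spectral == pytest.approx(np.sum(epoch.samples[c] ** 2), rel=1e-10)


class TestBandSelection:
    @pytest.mark.parametrize("window_s,expected_bins", [(3.0, 78), (2.0, 52), (1.6, 42)])
    def test_bin_counts_for_6_32_band(self, window_s, expected_bins):
        epoch = extract_window(sinusoid_epoch(10.0), window_s)
        feats = select_band(magnitude_spectrum(epoch))
        assert feats.values.shape == (3, expected_bins)
        assert feats.freq_axis[0] >= 6.0 and feats.freq_axis[-1] < 32.0

    def test_half_open_convention_excludes_32(self):
        epoch = extract_window(sinusoid_epoch(10.0), 3.0)
        feats = select_band(magnitude_spectrum(epoch), BandSpec(6.0, 32.0))
        assert feats.freq_axis[0] == pytest.approx(6.0)
        assert feats.freq_axis[-1] == pytest.approx(32.0 - 1 / 3)

    def test_empty_band_raises(self):
        with pytest.raises(ValueError):
            BandSpec(10.0, 10.0)

    def test_out_of_range_band_raises(self):
        epoch = extract_window(sinusoid_epoch(10.0), 3.0)
        with pytest.raises(ValueError, match="no bins"):
            select_band(magnitude_spectrum(epoch), BandSpec(200.0, 210.0))


class TestMinMax:
    def make_feats(self, values):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        return FeatureEpoch(values, np.arange(values.shape[1]) + 1.0, 0)

    def test_affine_map(self):
        out = minmax_normalize(self.make_feats([2.0, 4.0, 6.0]))
        assert np.allclose(out.values, [[0.0, 0.5, 1.0]])

    def test_constant_channel_maps_to_zeros(self):
        out = minmax_normalize(self.make_feats([3.0, 3.0, 3.0]))
        assert np.all(out.values == 0)

    def test_idempotent_on_spanning_unit_data(self):
        first = minmax_normalize(self.make_feats([2.0, 4.0, 6.0]))
        again = minmax_normalize(
            FeatureEpoch(first.values, first.freq_axis, 0, normalized=False)
        )
        assert np.array_equal(first.values, again.values)

    def test_double_normalization_rejected(self):
        first = minmax_normalize(self.make_feats([1.0, 2.0]))
        with pytest.raises(ValueError, match="already normalized"):
            minmax_normalize(first)

    def test_per_channel_independence(self):
        feats = FeatureEpoch(
            np.array([[0.0, 10.0], [5.0, 6.0]]), np.array([1.0, 2.0]), 0
        )
        out = minmax_normalize(feats)
        assert np.allclose(out.values, [[0.0, 1.0], [0.0, 1.0]])


class TestPipeline:
    def test_3s_pipeline_yields_3x78_in_unit_interval(self, config):
        epoch = simulate_trial(config, 0, seed=1)
        feats = featurize(epoch, window_s=3.0)
        assert feats.values.shape == (3, 78)
        assert feats.values.min() >= 0.0 and feats.values.max() <= 1.0
        assert feats.normalized

    def test_high_snr_peak_preserved_for_all_classes(self, high_snr_config):
        for cls, freq in enumerate(high_snr_config.stim_freqs):
            epoch = simulate_trial(high_snr_config, cls, seed=10 + cls)
            feats = featurize(epoch, window_s=3.0)
            df = feats.freq_axis[1] - feats.freq_axis[0]
            for ch in range(3):
                peak = feats.freq_axis[np.argmax(feats.values[ch])]
                assert abs(peak - freq) <= df / 2 + 1e-9
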