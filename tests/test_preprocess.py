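"""Filtering, segmentation and spectrogram behaviour."""

import numpy as np
import pytest

from pdmotion.data import RoundAnnotation, SensorRecording
from pdmotion.preprocess import (apply_filter, compute_spectrogram,
                                 compute_spectrograms, design_bandpass_fir,
                                 filter_response_db, segment_windows,
                                 spectrogram_shape, ChannelZScore,
                                 SpectrogramMinMax)

FS = 64.0


def make_recording(duration_s, exclusions=(), n_rounds=1, fs=FS):
    n = int(duration_s * fs)
    sig = np.random.default_rng(0).standard_normal((n, 6))
    edges = np.linspace(0, duration_s, n_rounds + 1)
    rounds = [RoundAnnotation(i + 1, edges[i], edges[i + 1], 20, "OFF")
              for i in range(n_rounds)]
    return SensorRecording("S1", sig, fs, rounds, list(exclusions))


@pytest.fixture(scope="module")
def kernel():
    return design_bandpass_fir(0.5, 15.0, FS, 513)


class TestFilterDesign:
    def test_band_edges_at_minus_3db(self, kernel):
        lo, hi = filter_response_db(kernel, [0.5, 15.0], FS)
        assert lo == pytest.approx(-3.0, abs=0.5)
        assert hi == pytest.approx(-3.0, abs=0.5)

    def test_passband_flat_at_center(self, kernel):
        assert filter_response_db(kernel, [7.0], FS)[0] == pytest.approx(0.0, abs=0.5)

    def test_stopband_attenuation(self, kernel):
        assert filter_response_db(kernel, [30.0], FS)[0] <= -20.0

    def test_linear_phase_symmetry(self, kernel):
        assert np.array_equal(kernel, kernel[::-1])

    @pytest.mark.parametrize("low,high", [(0.0, 15.0), (15.0, 0.5), (0.5, 40.0)])
    def test_invalid_band_edges_rejected(self, low, high):
        with pytest.raises(ValueError):
            design_bandpass_fir(low, high, FS, 513)

    def test_even_tap_count_rejected(self):
        with pytest.raises(ValueError):
            design_bandpass_fir(0.5, 15.0, FS, 512)


class TestApplyFilter:
    def test_zero_in_zero_out(self, kernel):
        rec = make_recording(60)
        rec.signals[:] = 0.0
        assert np.allclose(apply_filter(rec, kernel).signals, 0.0)

    def test_passband_tone_preserved(self, kernel):
        rec = make_recording(60)
        t = np.arange(rec.signals.shape[0]) / FS
        rec.signals[:] = np.sin(2 * np.pi * 5.0 * t)[:, None]
        out = apply_filter(rec, kernel).signals[320:-320]  # ignore edges
        amp = np.abs(out).max()
        assert amp == pytest.approx(1.0, rel=0.1)

    def test_drift_removed(self, kernel):
        rec = make_recording(60)
        t = np.arange(rec.signals.shape[0]) / FS
        rec.signals[:] = np.sin(2 * np.pi * 0.05 * t)[:, None]
        out = apply_filter(rec, kernel).signals
        assert np.abs(out).max() <= 0.1  # >= 90% attenuation

    def test_length_preserved(self, kernel):
        rec = make_recording(30)
        assert apply_filter(rec, kernel).signals.shape == rec.signals.shape

    def test_kernel_longer_than_signal_rejected(self, kernel):
        rec = make_recording(5)
        with pytest.raises(ValueError):
            apply_filter(rec, kernel)


class TestSegmentation:
    def test_plain_recording_window_count(self):
        wins = segment_windows(make_recording(60))
        assert len(wins) == 12
        assert all(w.x_r.shape == (320, 6) for w in wins)

    def test_trailing_partial_discarded(self):
        assert len(segment_windows(make_recording(13))) == 2

    def test_exclusion_splits_interval(self):
        # [0,10) and [20,30) each give 2 windows; nothing straddles the cut
        wins = segment_windows(make_recording(30, exclusions=[(10.0, 20.0)]))
        assert len(wins) == 4
        starts = sorted(w.start_s for w in wins)
        assert starts == [0.0, 5.0, 20.0, 25.0]

    def test_windows_respect_round_boundaries(self):
        # 2 rounds of 12.5 s: each contributes floor(12.5/5)=2 windows
        wins = segment_windows(make_recording(25, n_rounds=2))
        assert len(wins) == 4
        assert sorted({w.round_index for w in wins}) == [1, 2]

    def test_conservation_of_window_counts(self):
        # total = sum over kept intervals of floor(len/5)
        rec = make_recording(47, exclusions=[(6.0, 9.0), (30.0, 31.0)])
        kept = [(0, 6), (9, 30), (31, 47)]
        expected = sum(int((b - a) // 5) for a, b in kept)
        assert len(segment_windows(rec)) == expected

    def test_dominant_activity_labelling(self):
        rec = make_recording(10)
        rec.rounds[0].activities = [("resting", 0.0, 4.0), ("ambulation", 4.0, 10.0)]
        wins = segment_windows(rec)
        assert [w.activity_label for w in wins] == ["resting", "ambulation"]


class TestSpectrogram:
    def test_shape_is_pure_function_of_config(self, stft_cfg):
        assert spectrogram_shape(FS, 5.0, stft_cfg) == (33, 43)
        x = np.random.default_rng(1).standard_normal((4, 320, 6))
        assert compute_spectrograms(x, stft_cfg).shape == (4, 33, 43, 6)

    def test_zero_window_hits_floor(self, stft_cfg):
        s = compute_spectrograms(np.zeros((1, 320, 6)), stft_cfg)
        assert np.all(s == stft_cfg.log_floor_db)

    def test_pure_tone_peaks_at_its_bin(self, stft_cfg):
        x = np.zeros((1, 320, 6))
        x[0, :, 0] = np.sin(2 * np.pi * 5.0 * np.arange(320) / FS)
        s = compute_spectrograms(x, stft_cfg)[0]
        # 5 Hz -> bin 5 with nfft=64 at 64 Hz
        assert np.all(s[:, :, 0].argmax(axis=0) == 5)

    def test_amplitude_scaling_shifts_db_exactly(self, stft_cfg):
        x = np.random.default_rng(2).standard_normal((2, 320, 6))
        s1 = compute_spectrograms(x, stft_cfg)
        s2 = compute_spectrograms(3.0 * x, stft_cfg)
        mask = s1 > stft_cfg.log_floor_db
        np.testing.assert_allclose(s2[mask] - s1[mask], 20 * np.log10(3.0),
                                   rtol=0, atol=1e-3)

    def test_window_longer_than_signal_rejected(self, stft_cfg):
        with pytest.raises(ValueError):
            compute_spectrograms(np.zeros((1, 32, 6)), stft_cfg)

    def test_single_window_api_axes(self, stft_cfg):
        spec = compute_spectrogram(np.zeros((320, 6)), stft_cfg)
        assert spec.x_s.shape == (33, 43, 6)
        assert spec.freq_axis[0] == 0.0 and spec.freq_axis[-1] == FS / 2
        assert len(spec.time_axis) == 43


class TestNormalizers:
    def test_zscore_roundtrip_stats(self):
        x = np.random.default_rng(3).normal(5.0, 3.0, size=(50, 320, 6))
        z = ChannelZScore().fit(x).transform(x)
        np.testing.assert_allclose(z.mean(axis=(0, 1)), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=(0, 1)), 1.0, atol=1e-10)

    def test_minmax_unit_range_on_train(self):
        x = np.random.default_rng(4).normal(size=(10, 33, 43, 6))
        m = SpectrogramMinMax().fit(x)
        t = m.transform(x)
        assert t.min() >= 0.0 and t.max() <= 1.0
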