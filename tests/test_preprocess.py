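"""Closed-form checks for the derived-signal computations."""

import numpy as np
import pytest

from ansq.errors import ConfigError, DataError, SignalQualityError
from ansq.preprocess import (BeatSeries, compute_heart_rate,
                             compute_map_series, compute_rmssd_series,
                             detect_r_peaks, normalize_pupil, notch_filter,
                             reject_ibi_artifacts, relative_luminance,
                             smooth_eda)


def _sine(freq, fs, dur):
    t = np.arange(int(dur * fs)) / fs
    return t, np.sin(2 * np.pi * freq * t)


class TestNotch:
    def test_60hz_attenuated_30db(self):
        fs = 1000.0
        t, x = _sine(60.0, fs, 10.0)
        y = notch_filter(x, fs)
        sel = (t > 1.0) & (t < 9.0)  # avoid filter edges
        atten = 20 * np.log10(np.abs(y[sel]).max() / np.abs(x[sel]).max())
        assert atten <= -30.0

    def test_1hz_passband_within_1pct(self):
        fs = 1000.0
        t, x = _sine(1.0, fs, 10.0)
        y = notch_filter(x, fs)
        sel = (t > 1.0) & (t < 9.0)
        assert np.abs(y[sel] - x[sel]).max() <= 0.01

    def test_all_zero_passthrough(self):
        out = notch_filter(np.zeros(1000), 1000.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_fs_too_low(self):
        with pytest.raises(ConfigError):
            notch_filter(np.zeros(100), fs=100.0)


def _impulse_train_ecg(beat_times, fs, dur, amp=1.0):
    n = int(dur * fs)
    t = np.arange(n) / fs
    ecg = np.zeros(n)
    for tb in beat_times:
        ecg += amp * np.exp(-0.5 * ((t - tb) / 0.008) ** 2)
    return ecg


class TestRPeaks:
    def test_regular_train_recovered(self):
        fs = 1000.0
        truth = np.arange(0.5, 29.5, 1.0)
        ecg = _impulse_train_ecg(truth, fs, 30.0)
        beats = detect_r_peaks(ecg, fs)
        assert beats.n_beats == truth.size
        assert np.abs(beats.r_peak_times - truth).max() <= 0.010

    def test_noisy_train_98pct_within_10ms(self, rng):
        fs = 1000.0
        truth = np.arange(0.5, 29.5, 1.0)
        ecg = _impulse_train_ecg(truth, fs, 30.0)
        snr = 10.0  # dB
        noise_sd = np.sqrt(np.mean(ecg**2) / 10 ** (snr / 10))
        ecg = ecg + rng.normal(0, noise_sd, ecg.size)
        beats = detect_r_peaks(ecg, fs)
        hits = sum(np.abs(beats.r_peak_times - tb).min() <= 0.010
                   for tb in truth)
        assert hits / truth.size >= 0.98

    def test_flat_line_is_error(self):
        with pytest.raises(SignalQualityError):
            detect_r_peaks(np.zeros(30_000), 1000.0)

    def test_beat_dropout_is_error(self):
        fs = 1000.0
        truth = np.concatenate([np.arange(0.5, 10.0, 1.0),
                                np.arange(25.0, 30.0, 1.0)])
        ecg = _impulse_train_ecg(truth, fs, 30.0)
        with pytest.raises(SignalQualityError):
            detect_r_peaks(ecg, fs)


class TestHeartRate:
    def test_constant_1000ms_is_60bpm(self):
        beats = BeatSeries(np.arange(0.0, 30.0, 1.0))
        hr = compute_heart_rate(beats)
        np.testing.assert_allclose(hr.v, 60.0)

    def test_constant_800ms_is_75bpm(self):
        beats = BeatSeries(np.arange(0.0, 30.0, 0.8))
        hr = compute_heart_rate(beats)
        np.testing.assert_allclose(hr.v, 75.0)

    def test_two_beats_minimum(self):
        with pytest.raises(DataError):
            compute_heart_rate(BeatSeries(np.array([1.0])))

    def test_uniform_grid(self):
        beats = BeatSeries(np.arange(0.0, 30.0, 1.0))
        hr = compute_heart_rate(beats, fs_out=4.0)
        np.testing.assert_allclose(np.diff(hr.t), 0.25)


class TestRMSSD:
    def test_alternating_800_850_is_50ms(self):
        # successive differences are ±50 ms everywhere -> RMSSD = 50 exactly
        ibi = np.tile([0.8, 0.85], 60)
        beats = BeatSeries(np.concatenate([[0.0], np.cumsum(ibi)]))
        r = compute_rmssd_series(beats)
        vals = r.v[np.isfinite(r.v)]
        assert vals.size > 0
        np.testing.assert_allclose(vals, 50.0, atol=1e-9)

    def test_hand_window_40_82ms(self):
        # ibi 800, 830, 790, 840 ms -> diffs {+30, -40, +50} ms
        ibi_s = np.array([0.800, 0.830, 0.790, 0.840])
        beats = BeatSeries(np.concatenate([[0.0], np.cumsum(ibi_s)]))
        r = compute_rmssd_series(beats, window_s=float(ibi_s.sum()),
                                 step_s=1.0)
        expected = np.sqrt((900 + 1600 + 2500) / 3)
        vals = r.v[np.isfinite(r.v)]
        assert vals.size == 1
        assert vals[0] == pytest.approx(expected, abs=1e-9)

    def test_constant_ibi_is_zero(self):
        beats = BeatSeries(np.arange(0.0, 130.0, 1.0))
        r = compute_rmssd_series(beats)
        vals = r.v[np.isfinite(r.v)]
        np.testing.assert_allclose(vals, 0.0, atol=1e-12)

    def test_short_recording_is_error(self):
        beats = BeatSeries(np.arange(0.0, 30.0, 1.0))
        with pytest.raises(DataError):
            compute_rmssd_series(beats)

    def test_artifact_gap_does_not_bridge(self):
        # one huge interval (dropout): differences across it must not enter
        t = np.concatenate([np.arange(0.0, 60.0, 1.0),
                            np.arange(64.0, 130.0, 1.0)])
        beats = BeatSeries(t)
        r = compute_rmssd_series(beats)
        vals = r.v[np.isfinite(r.v)]
        np.testing.assert_allclose(vals, 0.0, atol=1e-9)


class TestArtifactRejection:
    def test_out_of_bounds_removed(self):
        ibi = np.array([0.8] * 20 + [4.0] + [0.8] * 20)  # 4 s dropout
        beats = BeatSeries(np.concatenate([[0.0], np.cumsum(ibi)]))
        _, clean = reject_ibi_artifacts(beats)
        assert clean.max() <= 3000.0
        assert clean.size == 40

    def test_median_deviation_removed(self):
        ibi = np.array([0.8] * 20 + [1.2] + [0.8] * 20)  # 50% off median
        beats = BeatSeries(np.concatenate([[0.0], np.cumsum(ibi)]))
        _, clean = reject_ibi_artifacts(beats)
        assert np.abs(clean - 800.0).max() < 1.0


class TestMAP:
    def test_constant_pressure(self):
        fs = 1000.0
        bp = np.full(30_000, 93.33)
        beats = BeatSeries(np.arange(0.5, 29.5, 1.0))
        m = compute_map_series(bp, fs, beats)
        np.testing.assert_allclose(m.v, 93.33, rtol=1e-9)

    def test_sine_pulse_averages_out(self):
        # zero-mean pulse within each beat: MAP equals the base pressure
        fs = 1000.0
        beats = BeatSeries(np.arange(0.0, 30.0, 1.0))
        t = np.arange(30_000) / fs
        bp = 90.0 + 20.0 * np.sin(2 * np.pi * (t % 1.0))
        m = compute_map_series(bp, fs, beats)
        np.testing.assert_allclose(m.v, 90.0, atol=0.1)

    def test_square_wave_9333(self):
        # 120 mmHg for 1/3 of each beat, 80 for 2/3 -> MAP = 93.33
        fs = 900.0
        n_beats = 30
        one_beat = np.concatenate([np.full(300, 120.0), np.full(600, 80.0)])
        bp = np.tile(one_beat, n_beats)
        beats = BeatSeries(np.arange(0.0, n_beats + 0.5, 1.0))
        m = compute_map_series(bp, fs, beats)
        np.testing.assert_allclose(m.v, 93.3333, atol=0.01)

    def test_nonphysiologic_warns(self):
        fs = 1000.0
        beats = BeatSeries(np.arange(0.5, 29.5, 1.0))
        with pytest.warns(UserWarning, match="non-physiologic"):
            compute_map_series(np.full(30_000, 400.0), fs, beats)


class TestLuminance:
    def test_endpoints(self):
        assert relative_luminance([255, 255, 255])[0] == pytest.approx(1.0)
        assert relative_luminance([0, 0, 0])[0] == 0.0

    def test_red_coefficient(self):
        assert relative_luminance([255, 0, 0])[0] == pytest.approx(0.2126)

    def test_green_blue_coefficients(self):
        assert relative_luminance([0, 255, 0])[0] == pytest.approx(0.7152)
        assert relative_luminance([0, 0, 255])[0] == pytest.approx(0.0722)

    def test_bad_shape(self):
        with pytest.raises(DataError):
            relative_luminance(np.zeros((5, 4)))


class TestPupil:
    def test_slope_normalization(self, rng):
        n = 2000
        rgb = rng.uniform(0, 255, (n, 3))
        L = relative_luminance(rgb)
        pupil = 2.0 * L + 0.5
        out = normalize_pupil(pupil, rgb, fs=50.0)
        # dividing by the fitted slope 2 -> slope of output vs L is 1
        slope = np.polyfit(L, out.v, 1)[0]
        assert slope == pytest.approx(1.0, abs=1e-6)

    def test_constant_luminance_passthrough(self):
        rgb = np.tile([[100.0, 100.0, 100.0]], (100, 1))
        pupil = np.linspace(3.0, 4.0, 100)
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_pupil(pupil, rgb, fs=50.0)
        np.testing.assert_allclose(out.v, pupil)

    def test_tiny_slope_passthrough(self, rng):
        rgb = rng.uniform(0, 255, (500, 3))
        pupil = np.full(500, 4.0)  # no luminance dependence
        with pytest.warns(UserWarning, match="slope"):
            out = normalize_pupil(pupil, rgb, fs=50.0)
        np.testing.assert_allclose(out.v, pupil)

    def test_misaligned_streams(self):
        with pytest.raises(DataError):
            normalize_pupil(np.zeros(10), np.zeros((9, 3)))


class TestEDA:
    def test_smooth_preserves_mean(self, rng):
        fs = 1000.0
        eda = 2.0 + 0.01 * rng.normal(size=10_000)
        out = smooth_eda(eda, fs)
        assert out.v.mean() == pytest.approx(2.0, abs=0.01)
        assert out.fs_out == 4.0
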