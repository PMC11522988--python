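"""Formant/MFCC estimation and tensorization."""

import numpy as np
import pytest

from rhotic.acoustics import (
    FORMANT_FEATURES,
    STAT_ORDER,
    FeatureTensor,
    FormantTrack,
    MfccTrack,
    RhoticInterval,
    buffer_interval,
    burg_coefficients,
    estimate_formants,
    estimate_mfcc,
    median_view,
    optimize_ceiling_train,
    tensorize,
)
from rhotic.errors import DataError, ParameterError
from rhotic.synth import synthesize_audio

from conftest import make_speaker


class TestBufferInterval:
    def test_ten_ms_both_sides(self):
        out = buffer_interval(RhoticInterval(0.100, 0.200), 1.0)
        assert out.start_s == pytest.approx(0.090)
        assert out.end_s == pytest.approx(0.210)

    def test_clipped_at_file_start(self):
        out = buffer_interval(RhoticInterval(0.005, 0.100), 1.0)
        assert out.start_s == 0.0 and out.end_s == pytest.approx(0.110)

    def test_length_grows_by_20_ms_unclipped(self):
        iv = RhoticInterval(0.2, 0.3)
        out = buffer_interval(iv, 1.0)
        assert out.duration_s - iv.duration_s == pytest.approx(0.020)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(DataError):
            RhoticInterval(0.2, 0.2)


def _constant_audio(targets=(500.0, 1500.0, 2500.0, 3500.0, 4500.0), dur=0.3):
    times = np.arange(0, dur, 0.005)
    track = FormantTrack(times, np.tile(targets, (times.size, 1)))
    return synthesize_audio(track, f0_hz=120.0, sample_rate_hz=16000)


class TestBurg:
    def test_recovers_known_ar_poles(self, rng):
        # oracle: an AR(4) process with two known resonances
        fs = 10000.0
        poles = []
        for f, bw in ((700.0, 80.0), (2200.0, 120.0)):
            r = np.exp(-np.pi * bw / fs)
            poles += [r * np.exp(2j * np.pi * f / fs), r * np.exp(-2j * np.pi * f / fs)]
        a_true = np.real(np.poly(poles))
        from scipy import signal

        x = signal.lfilter([1.0], a_true, rng.normal(size=4000))
        a_est = burg_coefficients(x, 4)
        roots = np.roots(a_est)
        freqs = np.sort(np.angle(roots[np.imag(roots) > 0]) * fs / (2 * np.pi))
        assert freqs == pytest.approx([700.0, 2200.0], rel=0.02)

    def test_order_too_large_rejected(self):
        with pytest.raises(ParameterError):
            burg_coefficients(np.ones(10), 10)


class TestEstimateFormants:
    def test_recovers_constant_resonances_within_5pct(self):
        audio = _constant_audio()
        track = estimate_formants(audio, 16000, ceiling_hz=5000.0)
        med = np.nanmedian(track.formants, axis=0)
        for i, target in enumerate((500.0, 1500.0, 2500.0)):
            assert abs(med[i] - target) / target < 0.05

    def test_silence_gives_undefined_frames(self):
        track = estimate_formants(np.zeros(3200), 16000, ceiling_hz=5000.0)
        assert np.all(np.isnan(track.formants))

    def test_frame_count_matches_windowing(self):
        audio = _constant_audio(dur=0.3)
        track = estimate_formants(audio, 16000, ceiling_hz=5000.0, step_s=0.005)
        expected = int(np.floor(len(audio) / 16000 / 0.005))
        assert abs(track.n_frames - expected) <= 2

    def test_ceiling_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            estimate_formants(np.zeros(1600), 16000, ceiling_hz=9000.0)

    def test_too_short_segment_rejected(self):
        with pytest.raises(DataError):
            estimate_formants(np.zeros(20), 16000, ceiling_hz=5000.0)

    def test_transforms_follow_invariants(self):
        audio = _constant_audio()
        track = estimate_formants(audio, 16000, ceiling_hz=5000.0)
        ok = np.isfinite(track.formants[:, 1]) & np.isfinite(track.formants[:, 2])
        np.testing.assert_allclose(
            track.f3_minus_f2[ok], (track.formants[:, 2] - track.formants[:, 1])[ok]
        )
        assert track.delta_f3_minus_f2[0] == 0.0


class TestCeilingOptimization:
    def test_single_value_grid_returned(self):
        audio = _constant_audio()
        assert optimize_ceiling_train([(audio, 16000.0)], [4800.0]) == 4800.0

    def test_deterministic(self):
        audio = _constant_audio()
        grid = [4200.0, 5000.0, 5800.0]
        a = optimize_ceiling_train([(audio, 16000.0)], grid)
        b = optimize_ceiling_train([(audio, 16000.0)], grid)
        assert a == b

    def test_chosen_ceiling_not_worse_than_worst(self):
        """On child-scaled audio with known resonances, the selected ceiling's
        median F3 error is no worse than the worst ceiling in the grid."""
        spk = make_speaker(age=7.0)
        targets = tuple(f * spk.vt_scale for f in (500.0, 1500.0, 2500.0, 3500.0, 4500.0))
        audio = _constant_audio(targets)
        grid = [4000.0, 5000.0, 6000.0]
        chosen = optimize_ceiling_train([(audio, 16000.0)], grid)
        errs = {}
        for c in grid:
            track = estimate_formants(audio, 16000, ceiling_hz=c)
            errs[c] = abs(np.nanmedian(track.formants[:, 2]) - targets[2])
        assert errs[chosen] <= max(errs.values())

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            optimize_ceiling_train([(np.zeros(1600), 16000.0)], [])


class TestMfcc:
    def test_thirteen_coefficients_per_frame(self):
        audio = _constant_audio()
        track = estimate_mfcc(audio, 16000)
        assert track.coefficients.shape[1] == 13

    def test_gain_change_moves_only_c0(self):
        audio = _constant_audio()
        a = estimate_mfcc(audio, 16000).coefficients
        b = estimate_mfcc(2.0 * audio, 16000).coefficients
        assert not np.allclose(a[:, 0], b[:, 0])
        np.testing.assert_allclose(a[:, 1:], b[:, 1:], atol=1e-8)

    def test_frame_times_match_formant_track(self):
        audio = _constant_audio()
        mf = estimate_mfcc(audio, 16000)
        fo = estimate_formants(audio, 16000, ceiling_hz=8000.0)
        # same windowing grid; formant path resampled -> compare count and step
        assert mf.n_frames == fo.n_frames
        np.testing.assert_allclose(np.diff(mf.frame_times_s), 0.005, atol=1e-6)


class TestTensorize:
    def test_formant_and_mfcc_shapes(self):
        spk = make_speaker()
        from rhotic.synth import generate_formant_track

        ftrack = generate_formant_track(spk, True, seed=1)
        assert tensorize(ftrack).values.shape == (5, 10, 8)
        mtrack = MfccTrack(ftrack.frame_times_s, np.random.default_rng(0).normal(size=(ftrack.n_frames, 13)))
        assert tensorize(mtrack).values.shape == (13, 10, 8)

    def test_constant_track_statistics(self):
        times = np.arange(0, 0.2, 0.005)
        track = FormantTrack(times, np.full((times.size, 5), 777.0))
        t = tensorize(track)
        v = t.values[0]  # F1 slice: (10 windows, 8 stats)
        assert np.all(v[:, 0] == 777.0) and np.all(v[:, 1] == 777.0)
        assert np.all(v[:, 3] == 777.0) and np.all(v[:, 4] == 777.0)
        assert np.all(v[:, 2] == 0.0) and np.all(v[:, 5] == 0.0)
        assert np.all(v[:, 6] == 0.0) and np.all(v[:, 7] == 0.0)

    def test_one_frame_per_window_median_is_frame_value(self):
        times = np.linspace(0, 0.9, 10)
        vals = np.arange(10, dtype=float)[:, None] * np.ones((1, 5))
        t = tensorize(FormantTrack(times, vals))
        np.testing.assert_allclose(t.values[0, :, 0], np.arange(10.0))

    def test_stat_consistency_min_median_max_and_variance(self, rng):
        times = np.arange(0, 0.3, 0.005)
        vals = rng.normal(2000, 100, size=(times.size, 5))
        t = tensorize(FormantTrack(times, vals))
        v = t.values
        assert np.all(v[:, :, 3] <= v[:, :, 0] + 1e-12)
        assert np.all(v[:, :, 0] <= v[:, :, 4] + 1e-12)
        np.testing.assert_allclose(v[:, :, 5], v[:, :, 2] ** 2, rtol=1e-10)

    def test_all_undefined_rejected(self):
        times = np.arange(0, 0.1, 0.005)
        with pytest.raises(DataError):
            tensorize(FormantTrack(times, np.full((times.size, 5), np.nan)))

    def test_empty_window_imputed_from_neighbours(self):
        # frames only in the first and last windows -> middle interpolated
        times = np.array([0.0, 0.01, 0.98, 1.0])
        vals = np.array([[100.0], [100.0], [200.0], [200.0]])

        class _T:
            frame_times_s = times
            feature_names = ("F3",)

            def feature_matrix(self):
                return vals

        t = tensorize(_T(), representation="formant")
        med = t.values[0, :, 0]
        assert np.all(np.isfinite(med))
        assert np.all(np.diff(med) >= 0)  # monotone ramp between the ends

    def test_median_view_is_stat_zero_slice(self):
        spk = make_speaker()
        from rhotic.synth import generate_formant_track

        t = tensorize(generate_formant_track(spk, True, seed=2))
        mv = median_view(t)
        assert mv.shape == (5, 10)
        np.testing.assert_array_equal(mv, t.values[:, :, 0])
        np.testing.assert_array_equal(mv, median_view(t))

    def test_stat_order_contract(self):
        assert STAT_ORDER[0] == "median" and len(STAT_ORDER) == 8
        assert FORMANT_FEATURES == ("F1", "F2", "F3", "F3-F2", "dF3-F2")
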