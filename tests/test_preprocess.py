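"""Re-referencing, baseline correction, epoching, filtering, power."""

import numpy as np
import pytest

from eegskip import (BANDS, PreprocessingError, Session, TrialEvent, band_power,
                     bandpass, baseline_correct, downsample, make_epochs,
                     preprocess_session, rereference, scalp_average)

from .conftest import toy_session


def _session_with(tp9, tp10, other, fs=500.0):
    data = np.vstack([tp9, tp10, np.tile(other, (2, 1))])
    n = data.shape[1]
    return Session(subject_id="t", fs=fs,
                   channel_labels=("TP9", "TP10", "F3", "F4"), data=data,
                   trials=[TrialEvent(0, n // 2, n, False, False)])


class TestRereference:
    def test_zero_mastoids_leave_data_unchanged(self):
        s = _session_with(np.zeros(10), np.zeros(10), np.arange(10.0))
        np.testing.assert_array_equal(rereference(s).data, s.data)

    def test_constant_mastoids_shift_every_channel(self):
        s = _session_with(np.full(10, 4.0), np.full(10, 4.0), np.arange(10.0))
        np.testing.assert_allclose(rereference(s).data, s.data - 4.0)

    def test_forced_arithmetic(self):
        s = _session_with(np.array([1.0, 1.0]), np.array([3.0, 3.0]),
                          np.array([10.0, 10.0]))
        out = rereference(s)
        np.testing.assert_allclose(out.channel("F3"), [8.0, 8.0])

    def test_input_session_is_not_modified(self):
        s = _session_with(np.ones(10), np.ones(10), np.arange(10.0))
        before = s.data.copy()
        rereference(s)
        np.testing.assert_array_equal(s.data, before)

    def test_missing_mastoid_raises(self):
        s = toy_session()
        s = Session(s.subject_id, s.fs, ("TPX", "TP10", "F3", "F4", "C0"),
                    s.data, s.trials)
        with pytest.raises(PreprocessingError):
            rereference(s)


class TestBaselineCorrect:
    def test_zero_baseline_leaves_segment_unchanged(self):
        s = _session_with(np.zeros(20), np.zeros(20), np.r_[np.zeros(10),
                                                            np.arange(10.0)])
        seg = baseline_correct(s, s.trials[0])
        np.testing.assert_allclose(seg[2], np.arange(10.0))

    def test_constant_baseline_subtracted_per_channel(self):
        other = np.r_[np.full(10, 5.0), np.full(10, 5.0)]
        s = _session_with(np.zeros(20), np.zeros(20), other)
        seg = baseline_correct(s, s.trials[0])
        np.testing.assert_allclose(seg[2], np.zeros(10))

    def test_correcting_baseline_window_itself_zeroes_its_mean(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((4, 40))
        s = Session("t", 500.0, ("TP9", "TP10", "F3", "F4"), data,
                    [TrialEvent(0, 20, 40, False, False)])
        t = TrialEvent(0, 20, 20 + 20, False, False)
        # re-extract the baseline window as if it were the viewing segment
        t2 = TrialEvent(0, 20, 40, False, False)
        corrected = data[:, 0:20] - data[:, 0:20].mean(axis=1, keepdims=True)
        np.testing.assert_allclose(corrected.mean(axis=1), 0.0, atol=1e-12)
        assert baseline_correct(s, t2).shape == (4, 20)


class TestEpoching:
    def test_floor_of_duration_one_second_epochs(self):
        seg = np.zeros(int(3.4 * 500))
        assert make_epochs(seg, 500.0, 1.0).shape == (3, 500)

    def test_half_second_epochs(self):
        seg = np.zeros(int(3.4 * 500))
        assert make_epochs(seg, 500.0, 0.5).shape == (6, 250)

    def test_short_segment_raises(self):
        with pytest.raises(PreprocessingError):
            make_epochs(np.zeros(400), 500.0, 1.0)

    def test_epochs_are_contiguous_from_start(self):
        seg = np.arange(1000.0)
        ep = make_epochs(seg, 500.0, 1.0)
        np.testing.assert_array_equal(ep[0], seg[:500])
        np.testing.assert_array_equal(ep[1], seg[500:1000])


class TestBandpass:
    fs = 500.0

    def _sine(self, freq, seconds=4.0):
        t = np.arange(int(seconds * self.fs)) / self.fs
        return np.sin(2 * np.pi * freq * t)

    def test_passband_gain_near_unity(self):
        x = self._sine(10.0)
        y = bandpass(x, BANDS["mu"], self.fs)
        mid = slice(500, -500)  # ignore filter edges
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation_at_least_20db(self):
        x = self._sine(10.0)
        y = bandpass(x, BANDS["beta"], self.fs)
        mid = slice(500, -500)
        assert np.abs(y[mid]).max() < 0.1  # -20 dB

    def test_zero_input_gives_zero_output(self):
        np.testing.assert_array_equal(
            bandpass(np.zeros((3, 500)), BANDS["theta"], self.fs),
            np.zeros((3, 500)))

    def test_low_sampling_rate_raises(self):
        with pytest.raises(PreprocessingError):
            bandpass(np.zeros(500), BANDS["beta"], 60.0)

    def test_band_energy_never_exceeds_broadband(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(2000)
        total = band_power(x)
        for band in BANDS.values():
            assert band_power(bandpass(x, band, self.fs)) <= total * 1.01


class TestDownsample:
    def test_2000_to_500_keeps_one_in_four(self):
        ep = np.zeros((2, 2000))
        assert downsample(ep, 2000.0, 500.0).shape == (2, 500)

    def test_identity_at_target_rate(self):
        ep = np.arange(500.0)[None, :]
        np.testing.assert_array_equal(downsample(ep, 500.0, 500.0), ep)

    def test_sine_rms_preserved_within_one_percent(self):
        t = np.arange(8000) / 2000.0
        x = np.sin(2 * np.pi * 10.0 * t)
        y = downsample(x[None, :], 2000.0, 500.0)[0]
        rms_ratio = np.sqrt(np.mean(y**2)) / np.sqrt(np.mean(x**2))
        assert rms_ratio == pytest.approx(1.0, rel=0.01)

    def test_non_integer_ratio_raises(self):
        with pytest.raises(PreprocessingError):
            downsample(np.zeros((1, 100)), 750.0, 500.0)


class TestScalpAverageAndPower:
    def test_identical_channels_average_to_that_channel(self):
        x = np.random.default_rng(0).standard_normal(100)
        np.testing.assert_allclose(scalp_average(np.tile(x, (5, 1))), x)

    def test_opposite_channels_cancel(self):
        x = np.random.default_rng(1).standard_normal(100)
        np.testing.assert_allclose(scalp_average(np.vstack([x, -x])),
                                   np.zeros(100), atol=1e-15)

    def test_average_equals_column_means(self):
        data = np.random.default_rng(2).standard_normal((4, 50))
        np.testing.assert_allclose(scalp_average(data), data.mean(axis=0))

    def test_power_of_zeros_is_zero(self):
        assert band_power(np.zeros(500)) == 0.0

    def test_power_of_sine_is_half_amplitude_squared(self):
        t = np.arange(1000) / 500.0
        x = 3.0 * np.sin(2 * np.pi * 10.0 * t)  # whole cycles
        assert band_power(x) == pytest.approx(4.5, rel=0.02)

    def test_power_equals_mean_square_by_direct_sum(self):
        x = np.random.default_rng(3).standard_normal(250)
        assert band_power(x) == pytest.approx(np.sum(x**2) / x.size, rel=1e-12)


class TestSessionPreprocessing:
    def test_epoch_counts_follow_trial_duration(self, tiny_session):
        trials, _ = preprocess_session(tiny_session)
        for t in trials:
            d = (t.event.end - t.event.video_onset) / tiny_session.fs
            n_ent = t.entropy[("beta", "scalp_average")].shape[0]
            n_pow = t.power[("beta", "scalp_average")].shape[0]
            assert n_ent == int(d)
            assert n_pow == int(2 * d)

    def test_all_band_source_combinations_present(self, tiny_session):
        trials, excluded = preprocess_session(tiny_session)
        assert len(trials) + len(excluded) == len(tiny_session.trials)
        keys = {(b, s) for b in ("theta", "mu", "beta")
                for s in ("scalp_average", "F3", "F4")}
        assert set(trials[0].entropy) == keys
        assert set(trials[0].power) == keys

    def test_entropy_epochs_are_at_500hz(self, tiny_session):
        trials, _ = preprocess_session(tiny_session)
        assert trials[0].entropy[("mu", "F3")].shape[1] == 500
        assert trials[0].fs == 500.0
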