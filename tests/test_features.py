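"""Index arithmetic, variability statistics, and the nine trial features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegskip import (DegenerateInputError, FeatureConfig, FEATURE_NAMES,
                     arousal_index, build_feature_row,
                     coefficient_of_variation, cv2_statistic, detect_peaks,
                     engagement_index, per_scale_feature_curves, range_of,
                     valence_index)
from eegskip.features import TrialFeatureData, build_feature_table, sliding_cv

positive = st.floats(0.1, 10.0, allow_nan=False)


class TestIndices:
    @pytest.mark.parametrize("beta,mu,theta,expected", [
        (1, 1, 1, 0.5), (2, 1, 1, 1.0), (0, 1, 1, 0.0)])
    def test_engagement_forced_cases(self, beta, mu, theta, expected):
        assert engagement_index(beta, mu, theta) == expected

    def test_engagement_zero_denominator_rejected(self):
        with pytest.raises(DegenerateInputError):
            engagement_index(1.0, 0.0, 0.0)

    @pytest.mark.parametrize("args,expected", [
        ((1, 1, 1, 1), 1.0), ((2, 2, 1, 1), 2.0)])
    def test_arousal_forced_cases(self, args, expected):
        assert arousal_index(*args) == expected

    @given(positive, positive, positive, positive)
    @settings(max_examples=30, deadline=None)
    def test_arousal_symmetric_under_hemisphere_swap(self, b3, b4, a3, a4):
        assert arousal_index(b3, b4, a3, a4) == \
            pytest.approx(arousal_index(b4, b3, a4, a3), rel=1e-12)

    @pytest.mark.parametrize("a3,b3,a4,b4,expected", [
        (1, 1, 1, 1, 0.0), (1, 1, 2, 1, 1.0)])
    def test_valence_forced_cases(self, a3, b3, a4, b4, expected):
        assert valence_index(a3, b3, a4, b4) == expected

    @given(positive, positive, positive, positive)
    @settings(max_examples=30, deadline=None)
    def test_valence_antisymmetric_under_hemisphere_swap(self, a3, b3, a4, b4):
        assert valence_index(a3, b3, a4, b4) == \
            pytest.approx(-valence_index(a4, b4, a3, b3), rel=1e-9, abs=1e-12)

    def test_valence_zero_beta_rejected(self):
        with pytest.raises(DegenerateInputError):
            valence_index(1.0, 0.0, 1.0, 1.0)


class TestVariabilityStatistics:
    def test_cv_of_constant_series_is_zero(self):
        assert coefficient_of_variation([4.0, 4.0, 4.0]) == 0.0

    def test_cv_hand_computed(self):
        # std([1,3], ddof=1) = sqrt(2); mean = 2
        assert coefficient_of_variation([1.0, 3.0]) == \
            pytest.approx(np.sqrt(2) / 2, abs=1e-12)

    @given(st.floats(0.1, 100.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_cv_scale_invariant(self, a, seed):
        x = np.random.default_rng(seed).uniform(1.0, 2.0, size=10)
        assert coefficient_of_variation(a * x) == \
            pytest.approx(coefficient_of_variation(x), rel=1e-9)

    def test_range_cases(self):
        assert range_of([5.0, 5.0]) == 0.0
        assert range_of([0.2, 0.9, 0.5]) == pytest.approx(0.7)
        assert range_of([3.0]) == 0.0
        x = np.random.default_rng(0).standard_normal(20)
        assert range_of(x) == range_of(-x)

    def test_peaks_constant_series_has_none(self):
        assert detect_peaks(np.ones(10)).size == 0

    def test_peaks_hand_example(self):
        x = [0, 10, 0, 12, 0, 0, 0, 0, 0, 0]  # mean 2.2, threshold 5.5
        np.testing.assert_array_equal(detect_peaks(x), [10, 12])

    def test_peak_must_exceed_factor_times_mean(self):
        np.testing.assert_array_equal(detect_peaks([0, 3, 0]), [3])
        assert detect_peaks([1, 3, 1]).size == 0  # 3 < 2.5 * (5/3)

    def test_cv2_fewer_than_two_peaks_is_zero(self):
        assert cv2_statistic([0, 10, 0, 0, 0, 0]) == 0.0
        assert cv2_statistic(np.ones(10)) == 0.0

    def test_cv2_hand_example(self):
        x = [0, 10, 0, 12, 0, 0, 0, 0, 0, 0]
        assert cv2_statistic(x) == pytest.approx(4 / 22, abs=1e-12)

    def test_cv2_equal_peaks_is_zero(self):
        x = [0, 8.0, 0, 8.0, 0, 8.0, 0, 0, 0, 0]
        assert cv2_statistic(x) == 0.0

    def test_cv2_bounded_for_positive_peaks(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = np.abs(rng.standard_normal(40)) ** 3
            assert 0.0 <= cv2_statistic(x) < 2.0


def _random_trial(seed, n_epochs=12, label_skip=1, label_interest=-1):
    rng = np.random.default_rng(seed)
    bands, sources = ("theta", "mu", "beta"), ("scalp_average", "F3", "F4")
    return TrialFeatureData(
        trial_index=0, label_skip=label_skip, label_interest=label_interest,
        entropies={(b, s): rng.uniform(0.5, 2.5, size=(n_epochs, 10))
                   for b in bands for s in sources},
        powers={(b, s): rng.uniform(0.5, 5.0, size=2 * n_epochs)
                for b in bands for s in sources},
    )


class TestFeatureRows:
    def test_constant_trial_gives_all_zero_features(self):
        bands, sources = ("theta", "mu", "beta"), ("scalp_average", "F3", "F4")
        data = TrialFeatureData(
            trial_index=0, label_skip=1, label_interest=1,
            entropies={(b, s): np.full((10, 10), 1.3) for b in bands
                       for s in sources},
            powers={(b, s): np.full(20, 2.0) for b in bands for s in sources},
        )
        row = build_feature_row(data, FeatureConfig())
        assert row is not None
        assert all(row[name] == 0.0 for name in FEATURE_NAMES)

    def test_identical_trials_give_identical_rows(self):
        a = build_feature_row(_random_trial(5), FeatureConfig())
        b = build_feature_row(_random_trial(5), FeatureConfig())
        assert a == b

    def test_short_trial_is_excluded(self):
        cfg = FeatureConfig()
        assert build_feature_row(_random_trial(1, n_epochs=cfg.cv_window),
                                 cfg) is None

    def test_row_matches_straight_line_recomputation(self):
        cfg = FeatureConfig()
        data = _random_trial(9, n_epochs=15)
        row = build_feature_row(data, cfg)

        ent = {k: v.mean(axis=1) for k, v in data.entropies.items()}
        for name, band in (("RCVB", "beta"), ("RCVM", "mu"), ("RCVT", "theta")):
            series = ent[(band, "scalp_average")]
            cvs = []
            for i in range(len(series) - cfg.cv_window + 1):
                w = series[i:i + cfg.cv_window]
                cvs.append(np.std(w, ddof=1) / np.mean(w))
            assert row[name] == pytest.approx(max(cvs) - min(cvs), rel=1e-12)

        eng = ent[("beta", "scalp_average")] / (
            ent[("mu", "scalp_average")] + ent[("theta", "scalp_average")])
        assert row["REEI"] == pytest.approx(eng.max() - eng.min(), rel=1e-12)
        aro = (ent[("beta", "F3")] + ent[("beta", "F4")]) / (
            ent[("mu", "F3")] + ent[("mu", "F4")])
        assert row["REAI"] == pytest.approx(aro.max() - aro.min(), rel=1e-12)
        val = (ent[("mu", "F4")] / ent[("beta", "F4")]
               - ent[("mu", "F3")] / ent[("beta", "F3")])
        assert row["REVI"] == pytest.approx(val.max() - val.min(), rel=1e-12)

        pw = data.powers
        eng_p = pw[("beta", "scalp_average")] / (
            pw[("mu", "scalp_average")] + pw[("theta", "scalp_average")])
        peaks = []
        for i in range(1, len(eng_p) - 1):
            if (eng_p[i] > eng_p[i - 1] and eng_p[i] > eng_p[i + 1]
                    and eng_p[i] > 2.5 * eng_p.mean()):
                peaks.append(eng_p[i])
        if len(peaks) < 2:
            expected = 0.0
        else:
            terms = [2 * abs(q - p) / (q + p) for p, q in zip(peaks, peaks[1:])]
            expected = sum(terms) / len(terms)
        assert row["CV2EI"] == pytest.approx(expected, rel=1e-12)

    def test_sliding_cv_length(self):
        out = sliding_cv(np.arange(1.0, 11.0), 5)
        assert out.size == 6


class TestPerScaleCurves:
    def test_identical_classes_give_zero_difference(self):
        trials = [_random_trial(3, label_skip=1), _random_trial(3, label_skip=-1)]
        curves = per_scale_feature_curves({"s01": trials}, "RCVB", "skip",
                                          FeatureConfig())
        assert len(curves) == 10
        np.testing.assert_allclose(curves["diff"], 0.0, atol=1e-12)

    def test_scale_one_curve_matches_single_scale_recomputation(self):
        cfg = FeatureConfig()
        trials = [_random_trial(4, label_skip=1), _random_trial(5, label_skip=-1)]
        curves = per_scale_feature_curves({"s01": trials}, "REVI", "skip", cfg)
        table = build_feature_table("s01", trials, cfg, scale=1)
        pos = table.loc[table["label_skip"] == 1, "REVI"].mean()
        assert curves.loc[curves["scale"] == 1, "mean_pos"].iloc[0] == \
            pytest.approx(pos, rel=1e-12)

    def test_power_feature_rejected(self):
        with pytest.raises(Exception):
            per_scale_feature_curves({"s01": [_random_trial(1)]}, "CV2EI",
                                     "skip", FeatureConfig())
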