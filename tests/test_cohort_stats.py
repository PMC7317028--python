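import itertools

import numpy as np
import pandas as pd
import pytest

from fmsf import (
    correlation_with_normality_gate,
    flag_disturbed_response,
    paired_signed_rank,
    regression_prediction_band,
    summarize_cohort,
    within_subject_cv,
)
from fmsf.synthetic import simulate_cohort


def enumerate_signed_rank_p(diffs):
    """Exact two-tailed signed-rank p by full enumeration of sign flips."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    count = 0
    total = 2 ** n
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestWithinSubjectCV:
    def test_printed_repeat_pair(self):
        # two repeats 144 and 187: SD/mean = 30.406/165.5 = 18.4%
        res = within_subject_cv({"043": [144.0, 187.0]})
        assert res.per_subject_cv["043"] == pytest.approx(0.1837, abs=5e-5)
        assert round(100 * res.mean_cv, 1) == 18.4

    def test_identical_repeats_give_zero(self):
        assert within_subject_cv({"a": [88.0, 88.0]}).mean_cv == 0.0

    def test_mean_cv_is_hand_computed_average(self):
        repeats = {"a": [10.0, 12.0], "b": [50.0, 40.0], "c": [5.0, 5.0, 8.0]}
        res = within_subject_cv(repeats)
        expected = np.mean([np.std(v, ddof=1) / np.mean(v)
                            for v in repeats.values()])
        assert res.mean_cv == pytest.approx(expected, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            within_subject_cv({"a": [1.0]})
        with pytest.raises(ValueError, match="zero mean"):
            within_subject_cv({"a": [-1.0, 1.0]})

    def test_scale_invariance(self):
        base = {"a": [144.0, 187.0], "b": [30.0, 45.0]}
        scaled = {k: [7.3 * x for x in v] for k, v in base.items()}
        assert within_subject_cv(base).mean_cv == pytest.approx(
            within_subject_cv(scaled).mean_cv, rel=1e-12)


class TestNormalityGatedCorrelation:
    def test_gaussian_linear_uses_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 40)
        y = 2 * x + rng.normal(0, 0.05, 40)
        res = correlation_with_normality_gate(x, y)
        assert res.method == "pearson"
        assert res.r > 0.99
        assert res.p < 1e-10

    def test_heavy_tailed_monotone_uses_spearman(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(0, 1.5, 40)
        y = x ** 3
        res = correlation_with_normality_gate(x, y)
        assert res.method == "spearman"
        assert res.r == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_with_normality_gate(np.ones(10), np.arange(10.0))

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(0, 1.5, 30)
        y = rng.lognormal(0, 1.5, 30)
        r1 = correlation_with_normality_gate(x, y)
        r2 = correlation_with_normality_gate(np.log(x), y ** 3)
        assert r1.method == r2.method == "spearman"
        assert r1.r == pytest.approx(r2.r, rel=1e-12)


class TestPairedSignedRank:
    def test_all_positive_n10_exact(self):
        a = np.arange(1.0, 11.0)
        d = np.linspace(0.5, 5.0, 10)  # all positive, untied
        assert paired_signed_rank(a + d, a) == pytest.approx(2 * 0.5 ** 10,
                                                             rel=1e-12)

    def test_antisymmetric_differences_give_p_one(self):
        a = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        assert paired_signed_rank(a, np.zeros(6)) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed,n", [(0, 6), (1, 7), (2, 9)])
    def test_matches_full_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, n)
        p = paired_signed_rank(d, np.zeros(n))
        assert p == pytest.approx(enumerate_signed_rank_p(d), rel=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            paired_signed_rank(np.ones(6), np.ones(6))


class TestPredictionBand:
    def test_planted_outlier_is_flagged(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(20, 70, 40)
        y = 150 - 1.5 * x + rng.normal(0, 5, 40)
        y[17] += 10 * 5.0  # +10 residual SDs
        band = regression_prediction_band(x, y, ids=[f"s{i}" for i in range(40)])
        assert band.outlier_ids == ["s17"]

    def test_collinear_data_has_no_outliers(self):
        x = np.arange(10.0)
        band = regression_prediction_band(x, 3.0 + 2.0 * x)
        assert band.outlier_ids == []
        np.testing.assert_allclose(band.upper, band.lower, atol=1e-9)
        assert band.slope == pytest.approx(2.0)

    def test_bands_widen_away_from_mean_x(self):
        rng = np.random.default_rng(6)
        x = np.linspace(0, 10, 30)
        y = x + rng.normal(0, 1, 30)
        band = regression_prediction_band(x, y)
        widths = band.upper - band.lower
        assert widths[0] > widths[len(x) // 2]
        assert widths[-1] > widths[len(x) // 2]

    def test_matches_statsmodels_prediction_interval(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 25)
        y = 1 + 0.5 * x + rng.normal(0, 1, 25)
        band = regression_prediction_band(x, y, level=0.95)
        model = sm.OLS(y, sm.add_constant(x)).fit()
        frame = model.get_prediction(sm.add_constant(x)).summary_frame(alpha=0.05)
        np.testing.assert_allclose(band.lower, frame["obs_ci_lower"], rtol=1e-9)
        np.testing.assert_allclose(band.upper, frame["obs_ci_upper"], rtol=1e-9)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regression_prediction_band(np.ones(10), np.arange(10.0))


class TestDisturbedResponseFlag:
    def cohort(self, fm_r, pie):
        return pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(len(fm_r))],
            "fm_r": fm_r, "pie_myo_r": pie,
        })

    def test_planted_joint_lowest_flagged(self):
        rng = np.random.default_rng(8)
        fm_r = np.concatenate([rng.uniform(100, 300, 9), [20, 25, 30]])
        pie = np.concatenate([rng.uniform(0.5, 0.9, 9), [0.2, 0.25, 0.3]])
        flagged = flag_disturbed_response(self.cohort(fm_r, pie))
        assert sorted(flagged) == ["S10", "S11", "S9"]

    def test_disjoint_quartiles_give_empty_set(self):
        # lowest fm_r quartile subjects have the *highest* myogenic shares
        fm_r = np.array([10.0, 20.0, 100.0, 110.0, 120.0, 130.0, 140.0, 150.0])
        pie = np.array([0.9, 0.8, 0.2, 0.3, 0.5, 0.6, 0.65, 0.7])
        assert flag_disturbed_response(self.cohort(fm_r, pie)) == []

    def test_boundary_value_included(self):
        # n=5: the 0.25 quantile is exactly the 2nd order statistic
        fm_r = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pie = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        assert np.quantile(fm_r, 0.25) == 2.0
        flagged = flag_disturbed_response(self.cohort(fm_r, pie))
        assert sorted(flagged) == ["S0", "S1"]

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="pie_myo_r"):
            flag_disturbed_response(pd.DataFrame({
                "subject_id": list("abcd"), "fm_r": [1.0, 2, 3, 4]}))


class TestSummarizeCohort:
    def test_full_summary_on_simulated_cohort(self):
        table, planted = simulate_cohort(n=35, planted_disturbed=3, seed=9,
                                         n_repeats=2)
        out = summarize_cohort(table)
        assert out["n_subjects"] == 35
        assert 0 < out["fm_mean_cv"] < 1
        assert out["fm_repeatability"]["method"] in ("pearson", "spearman")
        assert out["fm_vs_age"]["r"] < 0
        assert out["fm_r_vs_sbp"]["r"] < 0
        assert out["fm_vs_fm_r_wilcoxon_p"] < 0.01  # FM(R) systematically higher
        assert sorted(out["disturbed_response_ids"]) == planted
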