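"""Discrimination, classification accuracy and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from gdmscreen import (
    c_statistic,
    calibration_curve,
    classification_measures,
    impute,
    pooled_c_statistic,
    ppv_npv_from_operating_point,
)
from gdmscreen.metrics import calibration_smooth, stacked_calibration
from gdmscreen.models import predicted_risk


def brute_force_c(risks, outcomes):
    """All-pairs concordance with ties counting one half."""
    r = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    cases, controls = r[y == 1], r[y == 0]
    diff = cases[:, None] - controls[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


class TestCStatistic:
    def test_printed_toy_example(self):
        assert c_statistic([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_all_ties_give_half(self):
        assert c_statistic([0.3] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_perfect_separation_gives_one(self):
        assert c_statistic([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            c_statistic([0.1, 0.2], [1, 1])

    def test_rank_method_equals_all_pairs_and_sklearn(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 200))
            risks = rng.choice(np.round(rng.random(20), 2), size=n)  # forces ties
            outcomes = rng.binomial(1, 0.3, n)
            if outcomes.sum() in (0, n):
                continue
            c = c_statistic(risks, outcomes)
            assert c == pytest.approx(brute_force_c(risks, outcomes), abs=1e-12)
            assert c == pytest.approx(roc_auc_score(outcomes, risks), abs=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.floats(0, 1, allow_nan=False), st.booleans()),
            min_size=4,
            max_size=60,
        )
    )
    def test_invariance_under_monotone_transforms(self, data):
        # round so distinct values stay distinct under exp() in float64
        risks = np.round([d[0] for d in data], 4)
        outcomes = np.array([int(d[1]) for d in data])
        if outcomes.sum() in (0, len(outcomes)):
            return
        c = c_statistic(risks, outcomes)
        # logit-like strictly increasing map, scaling, and ranks
        assert c_statistic(risks * 10, outcomes) == pytest.approx(c)
        assert c_statistic(np.exp(2 * risks), outcomes) == pytest.approx(c)
        from scipy.stats import rankdata
        assert c_statistic(rankdata(risks), outcomes) == pytest.approx(c)
        # complementing the score flips concordance
        assert c_statistic(1 - risks, outcomes) == pytest.approx(1 - c)

    def test_pooled_c_on_complete_cohort_is_degenerate(self, small_cohort):
        imp = impute(small_cohort, m=4, seed=1)
        risks = small_cohort["bmi"].to_numpy(dtype=float)
        pooled = pooled_c_statistic([risks] * 4, small_cohort["gdm"])
        assert pooled.B == 0.0
        assert pooled.qbar == pytest.approx(c_statistic(risks, small_cohort["gdm"]))


class TestClassificationMeasures:
    def test_two_by_two_arithmetic(self):
        flags = [1] * 2 + [1] + [0] + [0] * 6
        outcomes = [1] * 2 + [0] + [1] + [0] * 6
        rep = classification_measures(flags, outcomes)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (2, 1, 1, 6)
        assert rep.sensitivity.value == pytest.approx(2 / 3)
        assert rep.specificity.value == pytest.approx(6 / 7)
        assert rep.ppv.value == pytest.approx(2 / 3)
        assert rep.npv.value == pytest.approx(6 / 7)
        assert rep.n == 10

    def test_all_flagged_degenerates(self):
        rep = classification_measures([1, 1, 1, 1], [1, 0, 1, 0])
        assert rep.sensitivity.value == 1.0
        assert rep.specificity.value == 0.0
        assert rep.npv.value is None
        assert "low-risk" in rep.npv.undefined_reason

    def test_wilson_interval_brackets_estimate(self):
        rep = classification_measures([1, 0, 1, 0, 1, 0], [1, 0, 0, 1, 1, 0])
        s = rep.sensitivity
        assert s.ci_low < s.value < s.ci_high
        assert 0 <= s.ci_low and s.ci_high <= 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classification_measures([], [])

    def test_printed_operating_point_implies_printed_predictive_values(self):
        """Sens 0.71 / spec 0.73 at prevalence 181/3723 imply PPV ~0.12
        and NPV ~0.98 by the Bayes identities."""
        ppv, npv = ppv_npv_from_operating_point(0.71, 0.73, 181 / 3723)
        assert round(ppv, 2) == 0.12
        assert round(npv, 2) == 0.98


class TestCalibration:
    def test_constant_risk_bins_at_prevalence(self):
        y = np.array([0] * 90 + [1] * 10)
        points = calibration_curve(np.full(100, 0.1), y, n_bins=2)
        assert sum(p.count for p in points) == 100
        for p in points:
            assert p.mean_predicted == pytest.approx(0.1)
        pooled = sum(p.observed_proportion * p.count for p in points) / 100
        assert pooled == pytest.approx(0.1)

    def test_well_calibrated_simulation_hugs_diagonal(self, rng):
        """Outcomes drawn from the risks themselves: every equal-frequency
        bin sits within 3 binomial SDs of the diagonal at n = 50 000."""
        lp = rng.normal(-3, 1.2, 50_000)
        risks = predicted_risk(lp)
        y = (rng.random(len(risks)) < risks).astype(int)
        for p in calibration_curve(risks, y, n_bins=10):
            se = np.sqrt(p.mean_predicted * (1 - p.mean_predicted) / p.count)
            assert abs(p.observed_proportion - p.mean_predicted) < 3 * se

    def test_logit_doubling_shows_slope_below_one(self, rng):
        """Doubling risks on the logit scale spreads predictions: low bins
        under-predict, high bins over-predict."""
        lp = rng.normal(-3, 1.0, 50_000)
        risks_true = predicted_risk(lp)
        y = (rng.random(len(lp)) < risks_true).astype(int)
        points = calibration_curve(predicted_risk(2 * lp + 3), y, n_bins=10)
        assert points[0].observed_proportion > points[0].mean_predicted
        assert points[-1].observed_proportion < points[-1].mean_predicted

    def test_bin_count_validation(self):
        with pytest.raises(ValueError, match="n_bins"):
            calibration_curve([0.1, 0.2, 0.3], [0, 1, 0], n_bins=5)
        with pytest.raises(ValueError, match="n_bins"):
            calibration_curve([0.1, 0.2, 0.3], [0, 1, 0], n_bins=1)

    def test_counts_sum_to_n_with_ragged_bins(self, rng):
        risks = rng.random(103)
        y = rng.binomial(1, 0.3, 103)
        points = calibration_curve(risks, y, n_bins=10)
        assert sum(p.count for p in points) == 103

    def test_stacked_calibration_uses_all_rows(self, small_cohort):
        imp = impute(small_cohort, m=3, seed=5)
        points = stacked_calibration(
            imp, lambda t: t["bmi"] / 100.0, n_bins=5
        )
        assert sum(p.count for p in points) == 3 * len(small_cohort)

    def test_smoother_returns_monotone_x(self, rng):
        risks = rng.random(500)
        y = rng.binomial(1, risks)
        xs, ys = calibration_smooth(risks, y)
        assert np.all(np.diff(xs) >= 0)
        assert ys.min() >= 0 and ys.max() <= 1
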