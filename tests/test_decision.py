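"""Net benefit, decision curves, scenarios and reclassification."""

import numpy as np
import pytest

from gdmscreen import (
    decision_curve,
    impute,
    net_benefit,
    reclassification_table,
    scenario_fixed_fraction,
    scenario_fixed_sensitivity,
)
from gdmscreen.decision import DEFAULT_THRESHOLD_GRID


def brute_force_fixed_sensitivity(risks, outcomes, target):
    """Scan all candidate cut-offs for the largest with sens >= target."""
    r = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    best = None
    for t in np.unique(r):
        sens = np.sum((r >= t) & (y == 1)) / y.sum()
        if sens >= target and (best is None or t > best):
            best = t
    return best


class TestNetBenefit:
    def test_printed_toy_example(self):
        """n=10, 2 cases; flags capture TP 2, FP 1 at pt 0.2:
        NB = 0.2 - 0.1 * 0.25 = 0.175."""
        risks = np.array([0.9, 0.8, 0.5, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        outcomes = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        assert net_benefit(risks, outcomes, 0.2) == pytest.approx(0.175)

    def test_treat_all_closed_form(self, rng):
        y = rng.binomial(1, 0.3, 500)
        p = y.mean()
        for pt in (0.01, 0.1, 0.25):
            nb = net_benefit(np.ones(500), y, pt)
            assert nb == pytest.approx(p - (1 - p) * pt / (1 - pt), abs=1e-12)

    def test_no_flags_give_zero(self):
        assert net_benefit([0.01, 0.02], [1, 0], 0.5) == 0.0

    def test_threshold_domain_enforced(self):
        with pytest.raises(ValueError, match="threshold"):
            net_benefit([0.5], [1], 0.0)
        with pytest.raises(ValueError, match="threshold"):
            net_benefit([0.5], [1], 1.0)

    def test_nonincreasing_in_pt_for_fixed_flags(self, rng):
        y = rng.binomial(1, 0.2, 400)
        flags = rng.random(400) < 0.3
        grid = np.linspace(0.01, 0.5, 50)
        nbs = [net_benefit(None, y, pt, flags=flags) for pt in grid]
        assert np.all(np.diff(nbs) <= 1e-15)


class TestDecisionCurve:
    def test_degenerate_pooling_equals_single_cohort(self, small_cohort):
        imp = impute(small_cohort, m=3, seed=1)  # identical copies
        risk_fn = lambda t: t["bmi"].to_numpy() / 60.0
        curve = decision_curve({"bmi": risk_fn}, imp, grid=[0.02, 0.05, 0.1])
        y = small_cohort["gdm"].to_numpy(dtype=float)
        single = [net_benefit(risk_fn(small_cohort), y, pt) for pt in [0.02, 0.05, 0.1]]
        np.testing.assert_allclose(curve.curves["bmi"], single)

    def test_treat_none_zero_and_bounds(self, small_cohort):
        imp = impute(small_cohort, m=2, seed=2)
        curve = decision_curve({}, imp)
        prev = small_cohort["gdm"].mean()
        assert np.all(curve.curves["treat_none"] == 0.0)
        assert np.all(curve.curves["treat_all"] <= prev + 1e-12)
        pt = curve.thresholds
        np.testing.assert_allclose(
            curve.curves["treat_all"], prev - (1 - prev) * pt / (1 - pt), atol=1e-12
        )

    def test_small_pt_limit_approaches_sensitivity_times_prevalence(self, small_cohort):
        imp = impute(small_cohort, m=2, seed=3)
        risk_fn = lambda t: t["bmi"].to_numpy() / 60.0
        curve = decision_curve({"bmi": risk_fn}, imp, grid=[1e-6])
        y = small_cohort["gdm"].to_numpy(dtype=float)
        assert curve.curves["bmi"][0] == pytest.approx(y.mean(), abs=1e-4)

    def test_empty_grid_rejected(self, small_cohort):
        imp = impute(small_cohort, m=2, seed=4)
        with pytest.raises(ValueError, match="grid"):
            decision_curve({}, imp, grid=[])

    def test_default_grid_covers_informative_range(self):
        assert DEFAULT_THRESHOLD_GRID[0] == pytest.approx(0.005)
        assert DEFAULT_THRESHOLD_GRID[-1] == pytest.approx(0.30)
        assert 0.02 in np.round(DEFAULT_THRESHOLD_GRID, 6)
        assert 0.12 in np.round(DEFAULT_THRESHOLD_GRID, 6)


class TestScenarioFixedFraction:
    def test_distinct_risks_flag_exactly_top_k(self, rng):
        risks = rng.permutation(np.linspace(0.01, 0.99, 10))
        outcomes = (risks > 0.6).astype(int)
        res = scenario_fixed_fraction(risks, outcomes, 0.3)
        assert res.flagged_fraction == pytest.approx(0.3)
        top3 = np.sort(risks)[-3:]
        assert res.sensitivity == pytest.approx(
            np.sum((risks >= top3.min()) & (outcomes == 1)) / outcomes.sum()
        )

    def test_fraction_near_one_maximises_sensitivity(self, rng):
        risks = rng.random(200)
        outcomes = rng.binomial(1, 0.2, 200)
        res = scenario_fixed_fraction(risks, outcomes, 0.995)
        assert res.sensitivity == 1.0
        assert res.specificity < 0.01

    def test_rank_invariance_across_calibration(self, rng):
        """Two models with identical rankings give identical results."""
        risks = rng.random(300)
        outcomes = rng.binomial(1, 0.15, 300)
        a = scenario_fixed_fraction(risks, outcomes, 0.29)
        b = scenario_fixed_fraction(risks**3, outcomes, 0.29)  # monotone remap
        assert a.sensitivity == b.sensitivity
        assert a.flagged_fraction == b.flagged_fraction

    def test_attained_fraction_within_one_over_n(self, rng):
        for n in (97, 250, 500):
            risks = rng.random(n)
            outcomes = rng.binomial(1, 0.2, n)
            res = scenario_fixed_fraction(risks, outcomes, 0.29)
            assert abs(res.flagged_fraction - 0.29) <= 1 / n

    def test_constant_risks_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            scenario_fixed_fraction([0.1] * 10, [0, 1] * 5, 0.3)


class TestScenarioFixedSensitivity:
    def test_toy_enumeration(self):
        """Case risks (0.9, 0.6, 0.2), target 2/3 -> threshold 0.6."""
        risks = np.array([0.9, 0.6, 0.2, 0.5, 0.3, 0.1])
        outcomes = np.array([1, 1, 1, 0, 0, 0])
        res = scenario_fixed_sensitivity(risks, outcomes, 2 / 3)
        assert res.threshold == pytest.approx(0.6)
        assert res.sensitivity == pytest.approx(2 / 3)
        assert res.flagged_fraction == pytest.approx(2 / 6)  # {0.9, 0.6}

    def test_target_one_flags_all_cases(self, rng):
        risks = rng.random(100)
        outcomes = rng.binomial(1, 0.3, 100)
        res = scenario_fixed_sensitivity(risks, outcomes, 1.0)
        assert res.sensitivity == 1.0
        assert res.threshold == pytest.approx(risks[outcomes == 1].min())

    def test_higher_target_never_flags_fewer(self, rng):
        risks = rng.random(400)
        outcomes = rng.binomial(1, 0.2, 400)
        fracs = [
            scenario_fixed_sensitivity(risks, outcomes, t).flagged_fraction
            for t in (0.5, 0.7, 0.9, 1.0)
        ]
        assert np.all(np.diff(fracs) >= 0)

    def test_matches_brute_force_scan(self, rng):
        """Sort-based threshold equals exhaustive scan at n <= 500."""
        for _ in range(25):
            n = int(rng.integers(20, 500))
            risks = np.round(rng.random(n), 3)  # ties likely
            outcomes = rng.binomial(1, 0.25, n)
            if outcomes.sum() == 0:
                continue
            for target in (0.5, 0.71, 0.9):
                res = scenario_fixed_sensitivity(risks, outcomes, target)
                assert res.threshold == pytest.approx(
                    brute_force_fixed_sensitivity(risks, outcomes, target)
                )

    def test_no_cases_rejected(self):
        with pytest.raises(ValueError, match="cases"):
            scenario_fixed_sensitivity([0.1, 0.2], [0, 0], 0.5)


class TestReclassification:
    def test_identical_classifiers_have_empty_off_diagonal(self, rng):
        flags = rng.random(50) < 0.3
        outcomes = rng.binomial(1, 0.2, 50)
        table = reclassification_table(flags, flags, outcomes)
        for (_, ref, mod), v in table["counts"].items():
            if ref != mod:
                assert v == 0

    def test_constructed_deltas(self):
        """Model flags one extra case and one fewer non-case than the
        reference on a 20-row toy."""
        outcomes = np.array([1] * 4 + [0] * 16)
        ref = np.array([1, 1, 0, 0] + [1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        model = np.array([1, 1, 1, 0] + [1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        table = reclassification_table(ref, model, outcomes)
        assert table["additional_cases_flagged"] == 1
        assert table["fewer_noncases_flagged"] == 1

    def test_cells_reproduce_marginal_two_by_twos(self, rng):
        ref = rng.random(200) < 0.3
        model = rng.random(200) < 0.25
        outcomes = rng.binomial(1, 0.2, 200)
        table = reclassification_table(ref, model, outcomes)
        counts = table["counts"]
        assert sum(counts.values()) == 200
        ref_high_cases = counts[("gdm", "high", "high")] + counts[("gdm", "high", "low")]
        assert ref_high_cases == int(np.sum(ref & (outcomes == 1)))
        model_high_noncases = (
            counts[("no_gdm", "high", "high")] + counts[("no_gdm", "low", "high")]
        )
        assert model_high_noncases == int(np.sum(model & (outcomes == 0)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            reclassification_table([1, 0], [1], [0, 1])
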