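"""Synthetic cohort generator: marginals, outcome mechanism, missingness."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gdmscreen import (
    GeneratorConfig,
    MissingnessConfig,
    apply_missingness,
    generate_cohort,
)
from gdmscreen.cohort import validate_cohort
from gdmscreen.models import intercept_only, logit
from gdmscreen.simulate import (
    GeneratorConfigError,
    MarDependence,
    default_missingness,
    generator_config_from_yaml,
    generator_config_to_yaml,
    lognormal_params_from_median_iqr,
)


@pytest.fixture(scope="module")
def big_cohort():
    return generate_cohort(GeneratorConfig(n_subjects=50_000, seed=42))


class TestGenerateCohort:
    def test_schema_valid_and_row_count(self, big_cohort):
        assert len(big_cohort) == 50_000
        assert validate_cohort(big_cohort, allow_missing=False) == []

    def test_default_prevalence_near_target(self, big_cohort):
        # target 181/3723 = 4.86%; 3 binomial SDs at n=50k ~ 0.29 pp
        target = 181 / 3723
        se = np.sqrt(target * (1 - target) / len(big_cohort))
        assert abs(big_cohort["gdm"].mean() - target) < 3 * se

    def test_marginals_recover_configured_values(self, big_cohort):
        n = len(big_cohort)
        cfg = GeneratorConfig()
        assert big_cohort["age_years"].mean() == pytest.approx(
            cfg.age_mean, abs=3 * cfg.age_sd / np.sqrt(n)
        )
        assert big_cohort["sbp_mmhg"].mean() == pytest.approx(
            cfg.sbp_mean, abs=3 * cfg.sbp_sd / np.sqrt(n)
        )
        # log-normal medians; SE of a sample median ~ 1.2533 sd/sqrt(n)
        _, bmi_sigma = lognormal_params_from_median_iqr(cfg.bmi_median, *cfg.bmi_iqr)
        tol = 3 * 1.2533 * bmi_sigma * cfg.bmi_median / np.sqrt(n)
        assert big_cohort["bmi"].median() == pytest.approx(cfg.bmi_median, abs=tol)
        assert big_cohort["glucose_mmol_l"].median() == pytest.approx(
            cfg.glucose_median, abs=0.05
        )
        for col, rate in (
            ("smoking", cfg.smoking_rate),
            ("family_history_dm", cfg.family_history_dm_rate),
            ("history_gdm", cfg.history_gdm_rate),
            ("history_macrosomia", cfg.history_macrosomia_rate),
        ):
            se = np.sqrt(rate * (1 - rate) / n)
            assert big_cohort[col].mean() == pytest.approx(rate, abs=3 * se)
        eth = big_cohort["ethnicity"].value_counts(normalize=True)
        assert eth["caucasian"] == pytest.approx(3387 / 3723, abs=0.01)
        assert (big_cohort["parity"] == 0).mean() == pytest.approx(1655 / 3723, abs=0.01)

    def test_bmi_identity_holds(self, big_cohort):
        resid = big_cohort["bmi"] - big_cohort["weight_kg"] / (
            big_cohort["height_cm"] / 100
        ) ** 2
        assert np.abs(resid).max() < 1e-9

    def test_history_fields_zero_for_nulliparous(self, big_cohort):
        nullip = big_cohort[big_cohort["parity"] == 0]
        assert nullip["history_gdm"].sum() == 0
        assert nullip["history_macrosomia"].sum() == 0

    def test_intercept_only_outcome_model(self):
        """All slopes zero + intercept logit(0.05) gives ~5% prevalence."""
        cfg = GeneratorConfig(
            n_subjects=50_000,
            seed=7,
            outcome_model=intercept_only(logit(0.05)),
            target_prevalence=None,
        )
        prev = generate_cohort(cfg)["gdm"].mean()
        assert prev == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / 50_000))

    def test_prevalence_tracks_mean_risk_for_any_outcome_model(self):
        """Empirical prevalence matches the mean inverse-logit at large n."""
        cfg = GeneratorConfig(n_subjects=100_000, seed=9, target_prevalence=0.10)
        cohort = generate_cohort(cfg)
        se = np.sqrt(0.10 * 0.90 / len(cohort))
        assert cohort["gdm"].mean() == pytest.approx(0.10, abs=3 * se)

    def test_seed_determinism(self):
        cfg = GeneratorConfig(n_subjects=500, seed=123)
        pd.testing.assert_frame_equal(generate_cohort(cfg), generate_cohort(cfg))

    def test_different_seeds_differ(self):
        a = generate_cohort(GeneratorConfig(n_subjects=500, seed=1))
        b = generate_cohort(GeneratorConfig(n_subjects=500, seed=2))
        assert not a.equals(b)

    def test_copula_induces_positive_correlation(self, big_cohort):
        sub = big_cohort[["age_years", "bmi", "glucose_mmol_l", "sbp_mmhg"]]
        corr = sub.corr().to_numpy()
        off = corr[np.triu_indices(4, k=1)]
        assert (off > 0.1).all() and (off < 0.4).all()

    @pytest.mark.parametrize(
        "field, value, match",
        [
            ("n_subjects", 0, "n_subjects"),
            ("age_sd", -1.0, "age_sd"),
            ("smoking_rate", 1.5, "smoking_rate"),
            ("target_prevalence", 0.0, "target_prevalence"),
        ],
    )
    def test_invalid_config_names_field(self, field, value, match):
        cfg = dataclasses.replace(GeneratorConfig(), **{field: value})
        with pytest.raises(GeneratorConfigError, match=match):
            generate_cohort(cfg)

    def test_bad_category_probabilities_rejected(self):
        cfg = GeneratorConfig()
        cfg.ethnicity_probs = {k: 0.2 for k in cfg.ethnicity_probs}  # sums to 1 but
        cfg.ethnicity_probs["caucasian"] = 0.3  # now 1.1
        with pytest.raises(GeneratorConfigError, match="ethnicity_probs"):
            generate_cohort(cfg)

    def test_generator_config_yaml_roundtrip(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=77, seed=3, copula_rho=0.1)
        path = tmp_path / "gen.yaml"
        generator_config_to_yaml(cfg, path)
        back = generator_config_from_yaml(path)
        assert back.n_subjects == 77 and back.copula_rho == 0.1
        pd.testing.assert_frame_equal(generate_cohort(back), generate_cohort(cfg))


class TestApplyMissingness:
    def test_zero_rates_identity(self, small_cohort):
        out = apply_missingness(small_cohort, MissingnessConfig(rates={}))
        pd.testing.assert_frame_equal(out, small_cohort)

    def test_mcar_rate_recovered(self):
        cohort = generate_cohort(GeneratorConfig(n_subjects=10_000, seed=5))
        cfg = MissingnessConfig(rates={"glucose_mmol_l": 0.2}, seed=6)
        out = apply_missingness(cohort, cfg)
        frac = out["glucose_mmol_l"].isna().mean()
        assert frac == pytest.approx(0.2, abs=3 * np.sqrt(0.2 * 0.8 / 10_000))
        assert out["gdm"].isna().sum() == 0

    def test_mar_weight_recovered_by_logistic_fit(self):
        """Missingness of glucose increasing in BMI: refitting the missing
        indicator on BMI recovers the configured weight within its CI."""
        cohort = generate_cohort(GeneratorConfig(n_subjects=40_000, seed=8))
        weight = 0.15
        cfg = MissingnessConfig(
            mechanism="MAR",
            rates={"glucose_mmol_l": 0.2},
            mar_dependence={"glucose_mmol_l": MarDependence("bmi", weight)},
            seed=9,
        )
        out = apply_missingness(cohort, cfg)
        ind = out["glucose_mmol_l"].isna().astype(float).to_numpy()
        X = sm.add_constant(cohort["bmi"].to_numpy())
        res = sm.Logit(ind, X).fit(disp=0)
        lo, hi = res.conf_int()[1]
        assert lo < weight < hi
        assert out["glucose_mmol_l"].isna().mean() == pytest.approx(0.2, abs=0.02)

    def test_mar_dependence_on_missing_column_rejected(self):
        cfg = MissingnessConfig(
            mechanism="MAR",
            rates={"glucose_mmol_l": 0.2, "bmi": 0.1},
            mar_dependence={"glucose_mmol_l": MarDependence("bmi", 0.1)},
        )
        with pytest.raises(GeneratorConfigError, match="itself set missing"):
            cfg.validate()

    def test_outcome_rate_rejected(self):
        with pytest.raises(GeneratorConfigError, match="gdm"):
            MissingnessConfig(rates={"gdm": 0.1}).validate()

    def test_missingness_determinism(self, small_cohort):
        cfg = default_missingness()
        a = apply_missingness(small_cohort, cfg)
        b = apply_missingness(small_cohort, cfg)
        pd.testing.assert_frame_equal(a, b)
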