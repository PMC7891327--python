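"""Synthetic maternal cohort generator.

Emulates a general low-risk first-trimester obstetric population of the
kind recruited through community midwifery care in north-western Europe:
~91% Caucasian, median pre-pregnancy BMI ~23 kg/m^2, GDM prevalence ~5%.
Defaults reproduce that population's marginals — age N(30.8, 4.2), SBP
N(115, 12), BMI log-normal with median 23.2 and IQR 21.1-26.2, random
venous glucose log-normal with median 4.7 and IQR 4.4-5.1 mmol/l (both
right-skewed), 44.5% nulliparous, 14.6% with a family history of diabetes,
1.6% with prior GDM, 6.2% with a prior macrosomic infant.

The outcome is drawn from a configurable logistic "true mechanism"
(a :class:`~gdmscreen.models.ModelSpec`); by default it loads on BMI, age,
ethnicity, histories and ln(glucose), and its intercept is auto-tuned by
bisection so the cohort's expected prevalence hits ``target_prevalence``.
Age, BMI, glucose and SBP share a Gaussian copula with a configurable
exchangeable correlation, so the glucose signal is partly redundant with
adiposity — as in real cohorts. Weight is back-solved from generated
height and BMI, preserving the BMI = weight / height(m)^2 identity.

A separate missingness stage (MCAR or MAR with a logistic dependence on a
covariate) punches holes for the imputation machinery to repair; the
outcome column is never made missing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import COLUMNS, CONCEPTION_LEVELS, EDUCATION_LEVELS, ETHNICITY_LEVELS
from .models import ModelSpec, Term, predicted_risk

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


class GeneratorConfigError(ValueError):
    """A generator or missingness configuration is invalid."""


def lognormal_params_from_median_iqr(
    median: float, iqr_low: float, iqr_high: float
) -> tuple[float, float]:
    """(meanlog, sdlog) of the log-normal matching a median and IQR.

    The IQR is matched in the symmetric-on-log-scale sense:
    sdlog = (ln q3 - ln q1) / (2 * z_0.75).
    """
    if not (0 < iqr_low < median < iqr_high):
        raise GeneratorConfigError(
            f"need 0 < q1 < median < q3, got ({iqr_low}, {median}, {iqr_high})"
        )
    return float(np.log(median)), float((np.log(iqr_high) - np.log(iqr_low)) / (2 * _Z75))


def default_outcome_model() -> ModelSpec:
    """Default true risk mechanism for the simulated outcome.

    Loads on the predictors the screening models share (BMI, age,
    ethnicity, history of GDM, family history) plus ln(glucose) with a
    genuine effect, so glucose carries added value over the clinical
    predictors. The intercept here is a placeholder; generation re-tunes
    it to the configured target prevalence.
    """
    return ModelSpec(
        name="custom",
        intercept=-9.0,
        terms=(
            Term("bmi", "identity", 0.09),
            Term("age_years", "identity", 0.03),
            Term("glucose_mmol_l", "natural_log", 2.0),
            Term("history_gdm", "identity", 2.2),
            Term("family_history_dm", "identity", 0.7),
            Term("ethnicity", "indicator", 1.0, "asian"),
            Term("ethnicity", "indicator", 0.5, "african"),
            Term("ethnicity", "indicator", 0.5, "other"),
            Term("ethnicity", "indicator", 0.2, "mixed"),
        ),
    )


def _table1_probs(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclass
class GeneratorConfig:
    """Settings for one synthetic cohort draw. Defaults emulate the
    target low-risk population's marginals (see module docstring)."""

    n_subjects: int = 3723
    seed: int = 0
    # continuous marginals
    age_mean: float = 30.8
    age_sd: float = 4.2
    sbp_mean: float = 115.0
    sbp_sd: float = 12.0
    bmi_median: float = 23.2
    bmi_iqr: tuple[float, float] = (21.1, 26.2)
    glucose_median: float = 4.7
    glucose_iqr: tuple[float, float] = (4.4, 5.1)
    height_mean: float = 168.7
    height_sd: float = 6.5
    # exchangeable Gaussian-copula correlation among age, BMI, glucose, SBP
    copula_rho: float = 0.25
    # categorical / binary marginals
    ethnicity_probs: dict[str, float] = field(
        default_factory=lambda: _table1_probs(
            {"caucasian": 3387, "african": 30, "asian": 53, "mixed": 77, "other": 176}
        )
    )
    education_probs: dict[str, float] = field(
        default_factory=lambda: _table1_probs({"low": 270, "medium": 1273, "high": 2180})
    )
    conception_probs: dict[str, float] = field(
        default_factory=lambda: _table1_probs(
            {"spontaneous": 3429, "ovulation_drugs": 99, "ivf": 110}
        )
    )
    smoking_rate: float = 334 / 3723
    family_history_dm_rate: float = 543 / 3723
    # parity pmf over 0,1,2,...; index = number of prior pregnancies
    parity_probs: tuple[float, ...] = (1655 / 3723, 0.36, 0.13, 0.045, 1 - 1655 / 3723 - 0.535)
    # marginal rates; realised only among parous women (parity >= 1)
    history_gdm_rate: float = 59 / 3723
    history_macrosomia_rate: float = 230 / 3723
    # outcome mechanism
    outcome_model: ModelSpec = field(default_factory=default_outcome_model)
    # if set, the outcome model's intercept is shifted by bisection so the
    # cohort-average risk equals this; if None the model is used as-is
    target_prevalence: float | None = 181 / 3723

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise GeneratorConfigError("n_subjects must be >= 1")
        for name in ("age_sd", "sbp_sd", "height_sd"):
            if getattr(self, name) <= 0:
                raise GeneratorConfigError(f"{name} must be positive")
        for name, probs, levels in (
            ("ethnicity_probs", self.ethnicity_probs, ETHNICITY_LEVELS),
            ("education_probs", self.education_probs, EDUCATION_LEVELS),
            ("conception_probs", self.conception_probs, CONCEPTION_LEVELS),
        ):
            if set(probs) != set(levels):
                raise GeneratorConfigError(f"{name} must have levels {levels}")
            if any(p < 0 for p in probs.values()):
                raise GeneratorConfigError(f"{name} has a negative probability")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise GeneratorConfigError(f"{name} must sum to 1 within 1e-9")
        if any(p < 0 for p in self.parity_probs) or abs(sum(self.parity_probs) - 1) > 1e-9:
            raise GeneratorConfigError("parity_probs must be non-negative and sum to 1")
        for name in (
            "smoking_rate",
            "family_history_dm_rate",
            "history_gdm_rate",
            "history_macrosomia_rate",
        ):
            rate = getattr(self, name)
            if not 0 <= rate <= 1:
                raise GeneratorConfigError(f"{name} must be in [0, 1]")
        parous = 1.0 - self.parity_probs[0]
        for name in ("history_gdm_rate", "history_macrosomia_rate"):
            if getattr(self, name) > parous + 1e-12:
                raise GeneratorConfigError(
                    f"{name} exceeds the parous fraction {parous:.4f}; "
                    "history fields are only realisable for parity >= 1"
                )
        if not -1 / 3 < self.copula_rho < 1:
            raise GeneratorConfigError("copula_rho must be in (-1/3, 1) for a valid 4x4 matrix")
        if self.target_prevalence is not None and not 0 < self.target_prevalence < 1:
            raise GeneratorConfigError("target_prevalence must be in (0, 1)")
        lognormal_params_from_median_iqr(self.bmi_median, *self.bmi_iqr)
        lognormal_params_from_median_iqr(self.glucose_median, *self.glucose_iqr)


def _tune_intercept_shift(lp: np.ndarray, target: float) -> float:
    """Bisection for delta with mean(expit(lp + delta)) = target."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(np.mean(predicted_risk(lp + mid))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Draw one complete synthetic cohort.

    Deterministic given ``config.seed``; identical configs give
    byte-identical tables. The outcome is Bernoulli with probability
    ``expit(linear predictor of config.outcome_model)``, intercept-shifted
    to ``target_prevalence`` when that is set.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    # correlated continuous block via Gaussian copula
    rho = config.copula_rho
    corr = np.full((4, 4), rho)
    np.fill_diagonal(corr, 1.0)
    z = rng.multivariate_normal(np.zeros(4), corr, size=n, method="cholesky")
    age = config.age_mean + config.age_sd * z[:, 0]
    bmi_mu, bmi_sigma = lognormal_params_from_median_iqr(config.bmi_median, *config.bmi_iqr)
    glu_mu, glu_sigma = lognormal_params_from_median_iqr(
        config.glucose_median, *config.glucose_iqr
    )
    bmi = np.exp(bmi_mu + bmi_sigma * z[:, 1])
    glucose = np.exp(glu_mu + glu_sigma * z[:, 2])
    sbp = config.sbp_mean + config.sbp_sd * z[:, 3]

    height = config.height_mean + config.height_sd * rng.standard_normal(n)
    weight = bmi * (height / 100.0) ** 2

    def draw_cat(probs: dict[str, float], levels: tuple[str, ...]) -> np.ndarray:
        p = np.array([probs[level] for level in levels])
        return np.asarray(levels)[rng.choice(len(levels), size=n, p=p / p.sum())]

    ethnicity = draw_cat(config.ethnicity_probs, ETHNICITY_LEVELS)
    education = draw_cat(config.education_probs, EDUCATION_LEVELS)
    conception = draw_cat(config.conception_probs, CONCEPTION_LEVELS)
    smoking = (rng.random(n) < config.smoking_rate).astype(int)
    family_history = (rng.random(n) < config.family_history_dm_rate).astype(int)

    parity_p = np.asarray(config.parity_probs, dtype=float)
    parity = rng.choice(len(parity_p), size=n, p=parity_p / parity_p.sum()).astype(int)
    parous = parity >= 1
    parous_frac = 1.0 - config.parity_probs[0]
    # conditional rates so the *marginal* rate matches the configured one
    gdm_cond = min(config.history_gdm_rate / parous_frac, 1.0) if parous_frac > 0 else 0.0
    mac_cond = min(config.history_macrosomia_rate / parous_frac, 1.0) if parous_frac > 0 else 0.0
    history_gdm = (parous & (rng.random(n) < gdm_cond)).astype(int)
    history_macrosomia = (parous & (rng.random(n) < mac_cond)).astype(int)

    df = pd.DataFrame(
        {
            "age_years": age,
            "height_cm": height,
            "weight_kg": weight,
            "bmi": bmi,
            "sbp_mmhg": sbp,
            "glucose_mmol_l": glucose,
            "ethnicity": ethnicity,
            "education": education,
            "smoking": smoking,
            "family_history_dm": family_history,
            "conception": conception,
            "parity": parity,
            "history_gdm": history_gdm,
            "history_macrosomia": history_macrosomia,
        }
    )

    lp = config.outcome_model.linear_predictor(df)
    if config.target_prevalence is not None:
        lp = lp + _tune_intercept_shift(lp, config.target_prevalence)
    df["gdm"] = (rng.random(n) < predicted_risk(lp)).astype(int)
    return df[list(COLUMNS)]


# ---------------------------------------------------------------------------
# Missingness


@dataclass
class MarDependence:
    """Missingness of one column depends logistically on another column:
    P(missing) = expit(alpha + weight * value), with alpha solved so the
    marginal missing rate equals the configured rate."""

    covariate: str
    weight: float


@dataclass
class MissingnessConfig:
    mechanism: str = "MCAR"  # MCAR | MAR
    rates: dict[str, float] = field(default_factory=dict)  # column -> rate in [0, 1)
    mar_dependence: dict[str, MarDependence] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.mechanism not in ("MCAR", "MAR"):
            raise GeneratorConfigError(f"unknown mechanism {self.mechanism!r}")
        for col, rate in self.rates.items():
            if col == "gdm":
                raise GeneratorConfigError("outcome column 'gdm' may never be made missing")
            if col not in COLUMNS:
                raise GeneratorConfigError(f"rates: unknown column {col!r}")
            if not 0 <= rate < 1:
                raise GeneratorConfigError(f"rates[{col!r}] must be in [0, 1)")
        if self.mechanism == "MAR":
            for col, dep in self.mar_dependence.items():
                if dep.covariate in self.rates and self.rates[dep.covariate] > 0:
                    raise GeneratorConfigError(
                        f"MAR dependence of {col!r} on {dep.covariate!r}, "
                        "but that covariate is itself set missing"
                    )
                if dep.covariate not in COLUMNS:
                    raise GeneratorConfigError(f"MAR covariate {dep.covariate!r} unknown")


def default_missingness() -> MissingnessConfig:
    """Modest missingness on the measured (staff-recorded) variables.

    The source study's per-variable missing-data table is supplementary
    and not transcribed here, so these MCAR rates are a free parameter:
    a few percent on glucose, blood pressure and weight, mirroring the
    pattern that questionnaire items are near-complete while clinical
    measurements are sporadically absent.
    """
    return MissingnessConfig(
        mechanism="MCAR",
        rates={"glucose_mmol_l": 0.05, "sbp_mmhg": 0.03, "weight_kg": 0.02, "bmi": 0.02},
    )


def _solve_mar_intercept(x: np.ndarray, weight: float, rate: float) -> float:
    lo, hi = -40.0 - abs(weight) * np.abs(x).max(), 40.0 + abs(weight) * np.abs(x).max()
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(np.mean(predicted_risk(mid + weight * x))) < rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def apply_missingness(cohort: pd.DataFrame, config: MissingnessConfig) -> pd.DataFrame:
    """Return a copy of the cohort with values blanked to NaN.

    MCAR: each configured cell is independently missing at its rate.
    MAR: the missing indicator for a column with a declared dependence
    follows ``expit(alpha + weight * covariate)`` with alpha calibrated to
    the marginal rate; columns without a dependence fall back to MCAR.
    The outcome column is never touched.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = cohort.copy()
    n = len(out)
    for col, rate in config.rates.items():
        if rate == 0:
            continue
        dep = config.mar_dependence.get(col) if config.mechanism == "MAR" else None
        if dep is not None:
            x = cohort[dep.covariate].to_numpy(dtype=float)
            if np.isnan(x).any():
                raise GeneratorConfigError(
                    f"MAR covariate {dep.covariate!r} has missing values"
                )
            alpha = _solve_mar_intercept(x, dep.weight, rate)
            p_missing = predicted_risk(alpha + dep.weight * x)
        else:
            p_missing = np.full(n, rate)
        mask = rng.random(n) < p_missing
        out.loc[mask, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# YAML round-trip for configs


def generator_config_to_yaml(config: GeneratorConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["outcome_model"] = {
        "name": config.outcome_model.name,
        "intercept": config.outcome_model.intercept,
        "terms": [dataclasses.asdict(t) for t in config.outcome_model.terms],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def generator_config_from_yaml(path) -> GeneratorConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "outcome_model" in d:
        m = d["outcome_model"]
        d["outcome_model"] = ModelSpec(
            name=m["name"],
            intercept=float(m["intercept"]),
            terms=tuple(Term(**t) for t in m.get("terms", [])),
        )
    for key in ("bmi_iqr", "glucose_iqr", "parity_probs"):
        if key in d:
            d[key] = tuple(d[key])
    return GeneratorConfig(**d)


def missingness_config_to_yaml(config: MissingnessConfig, path) -> None:
    d = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def missingness_config_from_yaml(path) -> MissingnessConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "mar_dependence" in d:
        d["mar_dependence"] = {
            k: MarDependence(**v) for k, v in (d["mar_dependence"] or {}).items()
        }
    return MissingnessConfig(**d)
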