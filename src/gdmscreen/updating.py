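"""Logistic recalibration and glucose extension of published risk models.

A published model is never refitted predictor-by-predictor here. Instead
its linear predictor lp is treated as a single offset-style covariate and

* recalibration fits ``logit P(y=1) = a + b * lp`` — the fitted ``a`` and
  ``b`` are the calibration intercept and calibration slope;
* extension adds first-trimester random venous glucose on the natural-log
  scale: ``logit P(y=1) = a + b * lp + g * ln(glucose)``, with all three
  coefficients re-estimated jointly;
* the added value of glucose is tested by the likelihood-ratio chi-square
  of the extended against the recalibrated fit (1 degree of freedom).

The classes follow the Model/Results convention: build a
:class:`ModelRecalibration` from a cohort and a
:class:`~gdmscreen.models.ModelSpec`, call :meth:`~ModelRecalibration.fit`
and read estimates, standard errors and a ``summary()`` off the results
object. :func:`fit_updated_models` runs the per-imputation fits over an
:class:`~gdmscreen.impute.ImputedSet` and Rubin-pools the coefficients.

With multiply imputed data there is no single accepted rule for pooling
likelihood-ratio tests; the combination reported here is deliberately
transparent: the per-imputation statistics, their median, and the fraction
of imputations significant at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import OUTCOME
from .impute import ImputedSet, PooledEstimate, rubin_pool
from .models import ModelSpec, predicted_risk


class FitError(RuntimeError):
    """A logistic fit failed (separation, degenerate design, ...)."""


def _fit_logit(X: np.ndarray, y: np.ndarray):
    """Newton-fit a logistic regression; raise FitError on degeneracy."""
    if len(np.unique(y)) < 2:
        raise FitError("outcome has a single class; recalibration undefined")
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            raise FitError(f"design column {j} is constant; linear predictor degenerate")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(method="newton", tol=1e-10, maxiter=100, disp=0)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as err:
        raise FitError(f"logistic fit failed: {err}") from err
    if not res.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge")
    params = np.asarray(res.params)
    if np.abs(params).max() > 1e3:
        raise FitError("coefficients diverged; data likely perfectly separated")
    return res


@dataclass
class RecalibrationResults:
    """Calibration intercept/slope of one model on one completed cohort."""

    model_name: str
    calibration_intercept: float
    calibration_slope: float
    intercept_var: float
    slope_var: float
    log_likelihood: float
    n: int
    null_log_likelihood: float

    @property
    def params(self) -> np.ndarray:
        return np.array([self.calibration_intercept, self.calibration_slope])

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt([self.intercept_var, self.slope_var])

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        p, se = self.params, self.bse
        return np.column_stack([p - z * se, p + z * se])

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Recalibration of {self.model_name} (n={self.n})",
            f"  calibration intercept  {self.calibration_intercept:8.4f}"
            f"  (95% CI {ci[0, 0]:.4f} to {ci[0, 1]:.4f})",
            f"  calibration slope      {self.calibration_slope:8.4f}"
            f"  (95% CI {ci[1, 0]:.4f} to {ci[1, 1]:.4f})",
            f"  log-likelihood         {self.log_likelihood:.4f}",
        ]
        return "\n".join(lines)


class ModelRecalibration:
    """Logistic recalibration of a published model on a complete cohort.

    Parameters
    ----------
    cohort
        Completed cohort table (no missing values among the model's
        predictors); the ``gdm`` column is the outcome.
    spec
        The published model whose linear predictor is recalibrated.
    """

    def __init__(self, cohort: pd.DataFrame, spec: ModelSpec):
        self.cohort = cohort
        self.spec = spec
        self.lp = np.asarray(spec.linear_predictor(cohort), dtype=float)
        self.y = cohort[OUTCOME].to_numpy(dtype=float)

    def fit(self) -> RecalibrationResults:
        X = np.column_stack([np.ones_like(self.lp), self.lp])
        res = _fit_logit(X, self.y)
        cov = np.asarray(res.cov_params())
        return RecalibrationResults(
            model_name=self.spec.name,
            calibration_intercept=float(res.params[0]),
            calibration_slope=float(res.params[1]),
            intercept_var=float(cov[0, 0]),
            slope_var=float(cov[1, 1]),
            log_likelihood=float(res.llf),
            n=len(self.y),
            null_log_likelihood=float(res.llnull),
        )


@dataclass
class ExtendedModelResults:
    """Recalibrated model jointly refitted with ln(glucose)."""

    model_name: str
    intercept: float
    lp_coefficient: float
    glucose_coefficient: float
    intercept_var: float
    lp_var: float
    glucose_var: float
    log_likelihood: float
    n: int

    @property
    def params(self) -> np.ndarray:
        return np.array([self.intercept, self.lp_coefficient, self.glucose_coefficient])

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt([self.intercept_var, self.lp_var, self.glucose_var])

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        p, se = self.params, self.bse
        return np.column_stack([p - z * se, p + z * se])

    def summary(self) -> str:
        ci = self.conf_int()
        rows = zip(
            ("intercept", "linear predictor", "ln(glucose)"), self.params, self.bse, ci
        )
        lines = [f"Glucose extension of {self.model_name} (n={self.n})"]
        for label, p, se, (lo, hi) in rows:
            lines.append(f"  {label:<18}{p:9.4f}  se {se:.4f}  (95% CI {lo:.4f} to {hi:.4f})")
        lines.append(f"  log-likelihood    {self.log_likelihood:.4f}")
        return "\n".join(lines)


class GlucoseExtension:
    """Joint refit of (recalibrated linear predictor, ln glucose)."""

    def __init__(self, cohort: pd.DataFrame, spec: ModelSpec):
        glucose = cohort["glucose_mmol_l"].to_numpy(dtype=float)
        if np.isnan(glucose).any():
            raise ValueError("glucose column has missing values; impute before extending")
        if (glucose <= 0).any():
            raise ValueError("glucose must be strictly positive for the log transform")
        self.cohort = cohort
        self.spec = spec
        self.lp = np.asarray(spec.linear_predictor(cohort), dtype=float)
        self.ln_glucose = np.log(glucose)
        self.y = cohort[OUTCOME].to_numpy(dtype=float)

    def fit(self) -> ExtendedModelResults:
        X = np.column_stack([np.ones_like(self.lp), self.lp, self.ln_glucose])
        res = _fit_logit(X, self.y)
        cov = np.asarray(res.cov_params())
        return ExtendedModelResults(
            model_name=self.spec.name,
            intercept=float(res.params[0]),
            lp_coefficient=float(res.params[1]),
            glucose_coefficient=float(res.params[2]),
            intercept_var=float(cov[0, 0]),
            lp_var=float(cov[1, 1]),
            glucose_var=float(cov[2, 2]),
            log_likelihood=float(res.llf),
            n=len(self.y),
        )


# functional façade ---------------------------------------------------------


def recalibrate(model: ModelSpec, cohort: pd.DataFrame) -> RecalibrationResults:
    """Fit outcome ~ intercept + slope * linear_predictor by ML."""
    return ModelRecalibration(cohort, model).fit()


def extend_with_glucose(model: ModelSpec, cohort: pd.DataFrame) -> ExtendedModelResults:
    """Fit outcome ~ intercept + b*lp + g*ln(glucose) by ML."""
    return GlucoseExtension(cohort, model).fit()


@dataclass
class LRTestResult:
    chi_square: float
    df: int
    p_value: float


def lr_test(loglik_nested: float, loglik_extended: float, df: int = 1) -> LRTestResult:
    """Likelihood-ratio chi-square test of nested logistic fits."""
    if df < 1:
        raise ValueError("df must be a positive integer")
    if loglik_extended < loglik_nested - 1e-6:
        raise ValueError(
            "extended log-likelihood below nested one beyond numerical tolerance; "
            "the models are not nested or a fit failed"
        )
    chi2 = max(2.0 * (loglik_extended - loglik_nested), 0.0)
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return LRTestResult(chi_square=chi2, df=df, p_value=p)


# pooled-over-imputations fitting -------------------------------------------


@dataclass
class PooledUpdatedModel:
    """One published model updated on an ImputedSet: Rubin-pooled
    recalibration and glucose-extension coefficients plus the
    per-imputation likelihood-ratio statistics for added glucose."""

    model_name: str
    calibration_intercept: PooledEstimate
    calibration_slope: PooledEstimate
    ext_intercept: PooledEstimate
    ext_lp_coefficient: PooledEstimate
    ext_glucose_coefficient: PooledEstimate
    lr_per_imputation: list[LRTestResult] = field(default_factory=list)
    per_imputation_recal: list[RecalibrationResults] = field(default_factory=list)
    per_imputation_ext: list[ExtendedModelResults] = field(default_factory=list)

    @property
    def lr_median_chi_square(self) -> float:
        return float(np.median([t.chi_square for t in self.lr_per_imputation]))

    @property
    def lr_median_p(self) -> float:
        return float(np.median([t.p_value for t in self.lr_per_imputation]))

    @property
    def lr_fraction_significant(self) -> float:
        ps = [t.p_value for t in self.lr_per_imputation]
        return float(np.mean([p < 0.05 for p in ps]))

    def recalibrated_risk(self, table: pd.DataFrame) -> np.ndarray:
        """Risk from the pooled recalibration applied to a table."""
        lp = np.asarray(self.base_spec.linear_predictor(table), dtype=float)
        return predicted_risk(
            self.calibration_intercept.qbar + self.calibration_slope.qbar * lp
        )

    def extended_risk(self, table: pd.DataFrame) -> np.ndarray:
        lp = np.asarray(self.base_spec.linear_predictor(table), dtype=float)
        lng = np.log(table["glucose_mmol_l"].to_numpy(dtype=float))
        return predicted_risk(
            self.ext_intercept.qbar
            + self.ext_lp_coefficient.qbar * lp
            + self.ext_glucose_coefficient.qbar * lng
        )

    base_spec: ModelSpec = None  # type: ignore[assignment]


def fit_updated_models(imputed: ImputedSet, spec: ModelSpec) -> PooledUpdatedModel:
    """Recalibrate and glucose-extend one model on every imputation and
    pool the coefficients by Rubin's rules."""
    recals: list[RecalibrationResults] = []
    exts: list[ExtendedModelResults] = []
    lrs: list[LRTestResult] = []
    for table in imputed:
        r = recalibrate(spec, table)
        e = extend_with_glucose(spec, table)
        recals.append(r)
        exts.append(e)
        lrs.append(lr_test(r.log_likelihood, e.log_likelihood, df=1))
    n = recals[0].n
    dfc = n - 2

    def pool(vals, var):
        return rubin_pool(vals, var, df_complete=dfc)

    return PooledUpdatedModel(
        model_name=spec.name,
        calibration_intercept=pool(
            [r.calibration_intercept for r in recals], [r.intercept_var for r in recals]
        ),
        calibration_slope=pool(
            [r.calibration_slope for r in recals], [r.slope_var for r in recals]
        ),
        ext_intercept=pool([e.intercept for e in exts], [e.intercept_var for e in exts]),
        ext_lp_coefficient=pool([e.lp_coefficient for e in exts], [e.lp_var for e in exts]),
        ext_glucose_coefficient=pool(
            [e.glucose_coefficient for e in exts], [e.glucose_var for e in exts]
        ),
        lr_per_imputation=lrs,
        per_imputation_recal=recals,
        per_imputation_ext=exts,
        base_spec=spec,
    )
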