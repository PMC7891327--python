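"""Discrimination, calibration and classification accuracy.

* c-statistic: probability that a randomly chosen case is assigned a
  higher risk than a randomly chosen non-case, ties counting one half —
  computed by a rank method (O(n log n)) that agrees exactly with the
  all-pairs definition. The per-sample variance uses the Hanley–McNeil
  formula so per-imputation c-statistics can be Rubin-pooled on the raw
  scale.
* classification measures: the 2x2 table of a binary screen against the
  outcome with sensitivity, specificity, PPV and NPV, each with a Wilson
  score interval.
* calibration: observed outcome proportion against mean predicted risk in
  equal-frequency risk bins, plus a fixed-span moving-average smoother;
  computed on the stacked imputations when plotting ("all imputed data
  sets as if they were one large data set").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .impute import ImputedSet, PooledEstimate, rubin_pool


def _as_arrays(risks, outcomes):
    r = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if r.shape != y.shape or r.ndim != 1:
        raise ValueError("risks and outcomes must be equal-length 1-d sequences")
    return r, y


def c_statistic(risks, outcomes) -> float:
    """Concordance probability via midranks; ties count one half.

    Equivalent to the Wilcoxon–Mann–Whitney statistic:
    ``(sum of case midranks - n1(n1+1)/2) / (n1 * n0)``.
    """
    r, y = _as_arrays(risks, outcomes)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("c-statistic undefined: outcomes contain a single class")
    ranks = stats.rankdata(r, method="average")
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def c_statistic_variance(c: float, n_cases: int, n_controls: int) -> float:
    """Hanley–McNeil (1982) variance of the c-statistic."""
    q1 = c / (2 - c)
    q2 = 2 * c**2 / (1 + c)
    return (
        c * (1 - c)
        + (n_cases - 1) * (q1 - c**2)
        + (n_controls - 1) * (q2 - c**2)
    ) / (n_cases * n_controls)


def pooled_c_statistic(risks_per_imputation, outcomes) -> PooledEstimate:
    """c-statistic per imputation, Rubin-pooled without transformation."""
    y = np.asarray(outcomes, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    cs, vs = [], []
    for risks in risks_per_imputation:
        c = c_statistic(risks, y)
        cs.append(c)
        vs.append(c_statistic_variance(c, n1, n0))
    return rubin_pool(cs, vs, df_complete=len(y) - 1)


@dataclass
class ProportionWithCI:
    value: float | None
    ci_low: float | None
    ci_high: float | None
    numerator: int
    denominator: int
    undefined_reason: str | None = None


def _wilson(numerator: int, denominator: int, reason_if_empty: str) -> ProportionWithCI:
    if denominator == 0:
        return ProportionWithCI(None, None, None, numerator, denominator,
                                undefined_reason=reason_if_empty)
    lo, hi = proportion_confint(numerator, denominator, alpha=0.05, method="wilson")
    return ProportionWithCI(numerator / denominator, float(lo), float(hi),
                            numerator, denominator)


@dataclass
class ClassificationReport:
    """2x2 screen-vs-outcome table with accuracy measures."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: ProportionWithCI = None  # type: ignore[assignment]
    specificity: ProportionWithCI = None  # type: ignore[assignment]
    ppv: ProportionWithCI = None  # type: ignore[assignment]
    npv: ProportionWithCI = None  # type: ignore[assignment]

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def flagged_fraction(self) -> float:
        return (self.tp + self.fp) / self.n

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.n


def classification_measures(flags, outcomes) -> ClassificationReport:
    """Cross-tabulate a binary screen against the outcome.

    Sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP) and
    NPV TN/(TN+FN), each with a Wilson score interval; a zero denominator
    yields an undefined measure carrying its reason rather than NaN.
    """
    f = np.asarray(flags).astype(bool)
    y = np.asarray(outcomes).astype(bool)
    if f.shape != y.shape or f.ndim != 1 or len(f) == 0:
        raise ValueError("flags and outcomes must be equal-length non-empty 1-d sequences")
    tp = int(np.sum(f & y))
    fp = int(np.sum(f & ~y))
    fn = int(np.sum(~f & y))
    tn = int(np.sum(~f & ~y))
    return ClassificationReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=_wilson(tp, tp + fn, "no cases in sample"),
        specificity=_wilson(tn, tn + fp, "no non-cases in sample"),
        ppv=_wilson(tp, tp + fp, "no subjects flagged high-risk"),
        npv=_wilson(tn, tn + fn, "no subjects flagged low-risk"),
    )


def ppv_npv_from_operating_point(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """Bayes identities: predictive values implied by an operating point.

    PPV = se*p / (se*p + (1-sp)(1-p)); NPV = sp(1-p) / ((1-se)p + sp(1-p)).
    """
    se, sp, p = sensitivity, specificity, prevalence
    ppv = se * p / (se * p + (1 - sp) * (1 - p))
    npv = sp * (1 - p) / ((1 - se) * p + sp * (1 - p))
    return ppv, npv


# ---------------------------------------------------------------------------
# Calibration


@dataclass
class CalibrationPoint:
    mean_predicted: float
    observed_proportion: float
    count: int


def calibration_curve(risks, outcomes, n_bins: int = 10) -> list[CalibrationPoint]:
    """Equal-frequency calibration bins.

    Rows are ranked by predicted risk (stable order, so duplicated values
    may straddle adjacent bins) and cut into ``n_bins`` near-equal groups;
    each point is (mean predicted risk, observed outcome proportion,
    bin count). Bin counts always sum to n.
    """
    r, y = _as_arrays(risks, outcomes)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n = len(r)
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds the number of subjects {n}")
    order = np.argsort(r, kind="stable")
    edges = np.linspace(0, n, n_bins + 1).round().astype(int)
    points = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        idx = order[lo:hi]
        points.append(
            CalibrationPoint(
                mean_predicted=float(r[idx].mean()),
                observed_proportion=float(y[idx].mean()),
                count=len(idx),
            )
        )
    return points


def calibration_smooth(risks, outcomes, span: float = 0.15, n_grid: int = 80):
    """Fixed-span moving local mean of the outcome along predicted risk.

    Returns (grid of predicted risks, smoothed observed proportion). The
    window covers ``span`` of the sample (by rank) around each grid point;
    deliberately a plain local average for reproducibility.
    """
    r, y = _as_arrays(risks, outcomes)
    order = np.argsort(r, kind="stable")
    r_sorted, y_sorted = r[order], y[order]
    n = len(r)
    half = max(int(span * n / 2), 1)
    centers = np.linspace(0, n - 1, min(n_grid, n)).round().astype(int)
    xs, ys = [], []
    for c in centers:
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        xs.append(float(r_sorted[lo:hi].mean()))
        ys.append(float(y_sorted[lo:hi].mean()))
    return np.asarray(xs), np.asarray(ys)


def stacked_calibration(imputed: ImputedSet, risk_fn, n_bins: int = 10):
    """Calibration points on the stacked imputations.

    ``risk_fn`` maps a completed table to a risk vector; the m tables are
    treated as one large data set for plotting.
    """
    risks = np.concatenate([np.asarray(risk_fn(t), dtype=float) for t in imputed])
    outcomes = np.concatenate([t["gdm"].to_numpy(dtype=float) for t in imputed])
    return calibration_curve(risks, outcomes, n_bins=n_bins)


def calibration_points_frame(points: list[CalibrationPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin": np.arange(1, len(points) + 1),
            "mean_pred": [p.mean_predicted for p in points],
            "obs_prop": [p.observed_proportion for p in points],
            "count": [p.count for p in points],
        }
    )
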