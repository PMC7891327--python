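"""Chained-equations multiple imputation and Rubin's-rules pooling.

Missing covariates are completed m times (default m = 10) by iterated
per-variable conditional draws — fully conditional specification, the
"mice" scheme. Continuous targets use proper Bayesian linear-regression
draws (posterior draw of the error variance and coefficients, then a noisy
prediction); binary targets a logistic fit with a coefficient draw and a
Bernoulli draw; categorical targets a multinomial-logistic probability
draw. Every imputation model conditions on all other covariates *and the
outcome*, per standard multiple-imputation guidance. Predictive-mean
matching is available as an option but is off by default.

Per-imputation estimates are pooled without transformation: the pooled
point estimate is the mean of the m estimates, within-imputation variance
W the mean of their variances, between-imputation variance B their sample
variance, and total variance T = W + (1 + 1/m)·B. Interval estimates use
the Barnard–Rubin small-sample degrees of freedom (normal reference as a
fallback).

BMI is never a chained-equations target: among (height, weight, BMI) any
single missing member is back-solved from BMI = weight / height(m)^2
before imputation, and BMI is recomputed afterwards where it was missing,
so the identity holds in every completed table and observed cells are
identical across imputations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CATEGORY_LEVELS, COLUMNS, OUTCOME, SCHEMA

#: continuous columns imputed on the log scale (keeps them positive)
_LOG_SCALE = {"glucose_mmol_l"}
_PMM_DONORS = 5


class ImputationError(ValueError):
    pass


@dataclass
class ImputedSet:
    """m completed copies of one cohort, sharing schema and row order."""

    tables: list[pd.DataFrame]
    seed: int | None = None
    iterations: int | None = None

    @property
    def m(self) -> int:
        return len(self.tables)

    def __iter__(self):
        return iter(self.tables)


def _resolve_bmi_triple(df: pd.DataFrame) -> pd.DataFrame:
    """Back-solve any single missing member of (height, weight, bmi)."""
    df = df.copy()
    h = df["height_cm"]
    w = df["weight_kg"]
    b = df["bmi"]
    hm, wm, bm = h.isna(), w.isna(), b.isna()
    only_b = bm & ~hm & ~wm
    df.loc[only_b, "bmi"] = w[only_b] / (h[only_b] / 100.0) ** 2
    only_w = wm & ~hm & ~bm
    df.loc[only_w, "weight_kg"] = b[only_w] * (h[only_w] / 100.0) ** 2
    only_h = hm & ~wm & ~bm
    df.loc[only_h, "height_cm"] = 100.0 * np.sqrt(w[only_h] / b[only_h])
    return df


def _encode_predictor(name: str, values: np.ndarray) -> list[np.ndarray]:
    """Encode one column into design-matrix pieces (dummies for categoricals)."""
    if SCHEMA[name] == "categorical":
        levels = CATEGORY_LEVELS[name]
        return [(values == lev).astype(float) for lev in levels[1:]]
    return [values.astype(float)]


def _design(data: dict[str, np.ndarray], predictors: list[str]) -> np.ndarray:
    pieces = [np.ones(len(next(iter(data.values()))))]
    for name in predictors:
        pieces.extend(_encode_predictor(name, data[name]))
    return np.column_stack(pieces)


def _bayes_linear_draw(
    X: np.ndarray, y: np.ndarray, Xmis: np.ndarray, rng: np.random.Generator, pmm: bool
) -> np.ndarray:
    """Proper Bayesian draw from the linear imputation model.

    Draws sigma^2 from its scaled inverse-chi-square posterior and beta
    from N(betahat, sigma^2 (X'X)^-1), then returns noisy predictions for
    the missing rows (or PMM donor values when pmm=True).
    """
    n, _ = X.shape
    # drop constant non-intercept columns (e.g. a category level absent
    # among the observed rows) and normalise column scales: both protect
    # the normal equations from singular / badly conditioned designs
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    Xk, Xm = X[:, keep], Xmis[:, keep]
    scale = np.sqrt(np.mean(Xk**2, axis=0))
    scale[scale == 0] = 1.0
    Xs = Xk / scale
    p = Xs.shape[1]
    xtx = Xs.T @ Xs + 1e-10 * np.eye(p)
    betahat = np.linalg.solve(xtx, Xs.T @ y)
    resid = y - Xs @ betahat
    df = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(df)
    cov = sigma2 * np.linalg.inv(xtx)
    try:
        beta = rng.multivariate_normal(betahat, cov, method="cholesky")
    except np.linalg.LinAlgError:
        beta = rng.multivariate_normal(betahat, cov, method="svd")
    mu_mis = (Xm / scale) @ beta
    X, Xmis = Xs, Xm / scale  # PMM donors use the same normalised space
    if pmm:
        mu_obs = X @ beta
        order = np.argsort(mu_obs, kind="stable")
        sorted_mu = mu_obs[order]
        idx = np.searchsorted(sorted_mu, mu_mis)
        out = np.empty(len(mu_mis))
        for i, (m_i, pos) in enumerate(zip(mu_mis, idx)):
            lo = max(pos - _PMM_DONORS, 0)
            hi = min(pos + _PMM_DONORS, n)
            cand = order[lo:hi]
            d = np.abs(mu_obs[cand] - m_i)
            donors = cand[np.argsort(d, kind="stable")[:_PMM_DONORS]]
            out[i] = y[donors[rng.integers(len(donors))]]
        return out
    return mu_mis + np.sqrt(sigma2) * rng.standard_normal(len(mu_mis))


def _logistic_draw(
    X: np.ndarray, y: np.ndarray, Xmis: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    import statsmodels.api as sm

    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    X, Xmis = X[:, keep], Xmis[:, keep]
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
            beta = rng.multivariate_normal(
                np.asarray(res.params), np.asarray(res.cov_params()), method="svd"
            )
        eta = Xmis @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    except Exception:
        p = np.full(Xmis.shape[0], y.mean())
    return (rng.random(Xmis.shape[0]) < p).astype(float)


def _multinomial_draw(
    X: np.ndarray, y: np.ndarray, Xmis: np.ndarray, levels: tuple[str, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression

    present = pd.unique(y)
    if len(present) == 1:
        return np.full(Xmis.shape[0], present[0], dtype=object)
    try:
        clf = LogisticRegression(max_iter=200, C=10.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X, y)
        proba = clf.predict_proba(Xmis)
        classes = clf.classes_
    except Exception:
        classes, counts = np.unique(y, return_counts=True)
        proba = np.tile(counts / counts.sum(), (Xmis.shape[0], 1))
    cum = np.cumsum(proba, axis=1)
    u = rng.random(Xmis.shape[0])[:, None]
    picks = (u > cum).sum(axis=1).clip(max=len(classes) - 1)
    return np.asarray(classes, dtype=object)[picks]


def impute(
    cohort: pd.DataFrame,
    m: int = 10,
    seed: int = 0,
    n_iter: int = 10,
    pmm: bool = False,
) -> ImputedSet:
    """Complete a cohort m times by chained equations.

    Deterministic given ``seed``: the m chains use independently spawned
    generators, each running ``n_iter`` full sweeps over the incomplete
    columns. A complete cohort returns m identical copies of the input.
    """
    if m < 2:
        raise ImputationError("m must be >= 2 for between-imputation variance")
    if cohort[OUTCOME].isna().any():
        raise ImputationError("outcome column must be complete")
    base = _resolve_bmi_triple(cohort)
    missing_cols = [c for c in base.columns if base[c].isna().any()]
    fully_missing = [c for c in missing_cols if base[c].isna().all()]
    if fully_missing:
        raise ImputationError(
            f"columns entirely missing, no conditional model possible: {fully_missing}"
        )
    if not missing_cols:
        return ImputedSet([cohort.copy() for _ in range(m)], seed=seed, iterations=n_iter)
    complete_covariates = [
        c for c in base.columns if c not in missing_cols and c != OUTCOME
    ]
    if not complete_covariates:
        raise ImputationError("need at least one complete covariate to condition on")

    targets = [c for c in missing_cols if c != "bmi"]
    bmi_missing = base["bmi"].isna().to_numpy()
    masks = {c: base[c].isna().to_numpy() for c in targets}
    predictors_of = {
        c: [p for p in COLUMNS if p not in (c, "bmi")] for c in targets
    }  # bmi excluded everywhere: collinear with height & weight

    seeds = np.random.SeedSequence(seed).spawn(m)
    tables: list[pd.DataFrame] = []
    for chain in range(m):
        rng = np.random.default_rng(seeds[chain])
        data = {c: base[c].to_numpy().copy() for c in base.columns}
        # initialise missing cells with draws from the observed values
        for c in targets:
            obs_vals = base[c].dropna().to_numpy()
            data[c][masks[c]] = obs_vals[rng.integers(len(obs_vals), size=masks[c].sum())]
        for _ in range(n_iter):
            for c in targets:
                mis = masks[c]
                obs = ~mis
                X_all = _design(data, predictors_of[c])
                Xobs, Xmis = X_all[obs], X_all[mis]
                kind = SCHEMA[c]
                if kind == "continuous":
                    y = base[c].to_numpy(dtype=float)[obs]
                    if c in _LOG_SCALE:
                        drawn = _bayes_linear_draw(Xobs, np.log(y), Xmis, rng, pmm)
                        data[c][mis] = np.exp(drawn)
                    else:
                        data[c][mis] = _bayes_linear_draw(Xobs, y, Xmis, rng, pmm)
                elif kind == "binary":
                    y = base[c].to_numpy(dtype=float)[obs]
                    data[c][mis] = _logistic_draw(Xobs, y, Xmis, rng)
                elif kind == "count":
                    y = base[c].to_numpy(dtype=float)[obs]
                    drawn = _bayes_linear_draw(Xobs, y, Xmis, rng, pmm)
                    data[c][mis] = np.clip(np.rint(drawn), 0, None)
                elif kind == "categorical":
                    y = base[c].to_numpy()[obs]
                    data[c][mis] = _multinomial_draw(
                        Xobs, y, Xmis, CATEGORY_LEVELS[c], rng
                    )
        table = pd.DataFrame(data, index=base.index)[list(base.columns)]
        # domain constraints the chained draws cannot see
        if "parity" in targets:
            must_be_parous = (table["history_gdm"] == 1) | (table["history_macrosomia"] == 1)
            fix = masks["parity"] & must_be_parous.to_numpy() & (table["parity"].to_numpy() == 0)
            table.loc[fix, "parity"] = 1
        if bmi_missing.any():
            h = table["height_cm"].to_numpy(dtype=float)
            w = table["weight_kg"].to_numpy(dtype=float)
            table.loc[bmi_missing, "bmi"] = (w / (h / 100.0) ** 2)[bmi_missing]
        for c in ("smoking", "family_history_dm", "history_gdm", "history_macrosomia",
                  "parity", OUTCOME):
            table[c] = table[c].astype(int)
        tables.append(table)
    return ImputedSet(tables, seed=seed, iterations=n_iter)


# ---------------------------------------------------------------------------
# Rubin's rules


@dataclass
class PooledEstimate:
    """Pooled estimate over m imputations (untransformed scale)."""

    qbar: float
    W: float
    B: float
    T: float
    m: int
    df: float = np.inf
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def se(self) -> float:
        return float(np.sqrt(self.T))


def rubin_pool(
    estimates,
    variances,
    alpha: float = 0.05,
    df_complete: float | None = None,
    small_sample: bool = True,
) -> PooledEstimate:
    """Pool per-imputation estimates by Rubin's rules.

    qbar is the mean of the estimates; W the mean within-imputation
    variance; B the (ddof=1) between-imputation variance;
    T = W + (1 + 1/m)·B. The confidence interval uses a Student-t
    reference with Barnard–Rubin degrees of freedom when ``small_sample``
    (requires ``df_complete`` for the observed-data adjustment; the
    classic (m-1)/lambda^2 value is used when that is not given, and a
    normal reference when ``small_sample`` is off or B = 0).
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length 1-d sequences")
    m = len(q)
    if m < 2:
        raise ValueError("pooling requires m >= 2 imputations")
    if (u < 0).any():
        raise ValueError("variances must be non-negative")
    qbar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    if T == 0.0:
        return PooledEstimate(qbar, W, B, T, m, df=np.inf, ci_low=qbar, ci_high=qbar)
    lam = (1.0 + 1.0 / m) * B / T
    if not small_sample or lam <= 0:
        dof = np.inf
        crit = stats.norm.ppf(1 - alpha / 2)
    else:
        df_old = (m - 1) / lam**2
        if df_complete is not None and np.isfinite(df_complete):
            df_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - lam)
            dof = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            dof = df_old
        crit = stats.t.ppf(1 - alpha / 2, dof)
    half = crit * np.sqrt(T)
    return PooledEstimate(qbar, W, B, T, m, df=float(dof),
                          ci_low=qbar - half, ci_high=qbar + half)


def stack(imputed: ImputedSet) -> pd.DataFrame:
    """Concatenate the m completed tables with an ``imputation`` index
    column (1-based); used for stacked calibration plotting."""
    frames = []
    for k, table in enumerate(imputed.tables, start=1):
        frame = table.copy()
        frame.insert(0, "imputation", k)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# serialization (long CSV + JSON sidecar)


def write_imputed(imputed: ImputedSet, csv_path, meta_path=None) -> None:
    stack(imputed).to_csv(csv_path, index=False, na_rep="")
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            json.dump(
                {"m": imputed.m, "seed": imputed.seed, "iterations": imputed.iterations},
                fh,
                indent=2,
            )


def read_imputed(csv_path, meta_path=None) -> ImputedSet:
    long = pd.read_csv(csv_path)
    tables = [
        grp.drop(columns="imputation").reset_index(drop=True)
        for _, grp in long.groupby("imputation", sort=True)
    ]
    seed = iterations = None
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
        seed, iterations = meta.get("seed"), meta.get("iterations")
    return ImputedSet(tables, seed=seed, iterations=iterations)
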