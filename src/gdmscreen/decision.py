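"""Decision-curve analysis and fixed-operating-point scenario comparisons.

Net benefit at a threshold probability pt weighs true against false
positives at the odds a decision-maker implies by testing at pt:

    NB(pt) = TP/n - (FP/n) * pt / (1 - pt)

A risk model flags subjects with risk >= pt; the rule-based reference
method has no risk scale, so its fixed flags are carried across the whole
threshold grid (NB still varies through the false-positive weight);
treat-all and treat-none close the curve family.

Two scenario comparisons pin the operating point to the reference method:
scenario A holds the flagged fraction constant (does the model find more
cases among the same number of screens?), scenario B holds sensitivity
constant (does the model need fewer screens to find the same cases?).
Both report the reclassification cross-tabulation — high/low by reference
x high/low by model, stratified by outcome — as eight counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .impute import ImputedSet

DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.005, 0.300001, 0.005), 6)


def net_benefit(risks, outcomes, pt: float, flags=None) -> float:
    """Net benefit at threshold probability pt.

    Flags are ``risk >= pt`` unless an explicit binary strategy is given
    (the reference method), in which case ``risks`` may be None.
    """
    if not 0.0 < pt < 1.0:
        raise ValueError(f"threshold probability must be in (0, 1), got {pt}")
    y = np.asarray(outcomes, dtype=float)
    if flags is None:
        r = np.asarray(risks, dtype=float)
        flags = r >= pt
    else:
        flags = np.asarray(flags).astype(bool)
    n = len(y)
    tp = float(np.sum(flags & (y == 1)))
    fp = float(np.sum(flags & (y == 0)))
    return tp / n - (fp / n) * pt / (1.0 - pt)


@dataclass
class DecisionCurve:
    """Net benefit per strategy over a threshold grid (pooled over
    imputations by averaging the per-imputation net benefits)."""

    thresholds: np.ndarray
    curves: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for strategy, nb in self.curves.items():
            for pt, v in zip(self.thresholds, nb):
                rows.append({"pt": pt, "strategy": strategy, "net_benefit": v})
        return pd.DataFrame(rows)


def decision_curve(
    strategies: dict,
    imputed: ImputedSet,
    grid=None,
    reference_flags_fn=None,
) -> DecisionCurve:
    """Decision curves for risk strategies plus treat-all/treat-none.

    ``strategies`` maps a name to a callable giving risks for a completed
    table; ``reference_flags_fn`` (optional) gives the reference method's
    fixed binary flags. Net benefit is computed per imputation and
    averaged across the m imputations.
    """
    grid = DEFAULT_THRESHOLD_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if ((grid <= 0) | (grid >= 1)).any():
        raise ValueError("threshold grid must lie inside (0, 1)")
    curves: dict[str, np.ndarray] = {}
    m = imputed.m

    def averaged(fn_nb):
        vals = np.zeros(len(grid))
        for table in imputed:
            y = table["gdm"].to_numpy(dtype=float)
            vals += fn_nb(table, y)
        return vals / m

    for name, risk_fn in strategies.items():
        def nb_model(table, y, risk_fn=risk_fn):
            r = np.asarray(risk_fn(table), dtype=float)
            return np.array([net_benefit(r, y, pt) for pt in grid])
        curves[name] = averaged(nb_model)

    if reference_flags_fn is not None:
        def nb_ref(table, y):
            flags = np.asarray(reference_flags_fn(table)).astype(bool)
            return np.array([net_benefit(None, y, pt, flags=flags) for pt in grid])
        curves["reference"] = averaged(nb_ref)

    def nb_all(table, y):
        p = y.mean()
        return p - (1 - p) * grid / (1 - grid)

    curves["treat_all"] = averaged(nb_all)
    curves["treat_none"] = np.zeros(len(grid))
    return DecisionCurve(thresholds=grid, curves=curves)


# ---------------------------------------------------------------------------
# Scenario comparisons


@dataclass
class ScenarioResult:
    scenario: str  # "A" (fixed flagged fraction) or "B" (fixed sensitivity)
    threshold: float
    flagged_fraction: float
    sensitivity: float
    specificity: float
    n: int
    reclassification: dict | None = None


def _summarise(flags: np.ndarray, y: np.ndarray, scenario: str, threshold: float):
    n = len(y)
    tp = int(np.sum(flags & (y == 1)))
    fp = int(np.sum(flags & (y == 0)))
    cases = int(y.sum())
    return ScenarioResult(
        scenario=scenario,
        threshold=float(threshold),
        flagged_fraction=float(flags.mean()),
        sensitivity=tp / cases,
        specificity=(n - cases - fp) / (n - cases),
        n=n,
    )


def scenario_fixed_fraction(risks, outcomes, target_fraction: float) -> ScenarioResult:
    """Scenario A: flag the top ``target_fraction`` of the risk ranking.

    The threshold is the smallest risk value such that the fraction with
    risk >= threshold does not exceed the target. With ties at the
    threshold the attained fraction is below the target; the attained
    (not target) fraction is reported.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must be in (0, 1)")
    r = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.ptp(r) == 0:
        raise ValueError(
            "all risks identical: no ranking can attain the target fraction"
        )
    n = len(r)
    k = int(np.floor(target_fraction * n + 1e-12))
    if k == 0:
        raise ValueError(f"target fraction {target_fraction} flags no subjects at n={n}")
    # flag by descending risk, ties broken by stable row order, until the
    # target count is met; the attained fraction k/n is reported
    order = np.argsort(-r, kind="stable")
    flags = np.zeros(n, dtype=bool)
    flags[order[:k]] = True
    threshold = float(r[order[k - 1]])
    return _summarise(flags, y, "A", threshold)


def scenario_fixed_sensitivity(risks, outcomes, target_sens: float) -> ScenarioResult:
    """Scenario B: the largest threshold whose sensitivity >= target.

    Maximising the threshold minimises the flagged fraction subject to
    catching at least the target share of cases.
    """
    if not 0.0 < target_sens <= 1.0:
        raise ValueError("target_sens must be in (0, 1]")
    r = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    case_risks = r[y == 1]
    if case_risks.size == 0:
        raise ValueError("no cases present; sensitivity undefined")
    k = int(np.ceil(target_sens * case_risks.size - 1e-12))
    sorted_case = np.sort(case_risks)[::-1]
    threshold = sorted_case[k - 1]  # >= threshold catches >= k cases
    flags = r >= threshold
    sens = float(np.sum(flags & (y == 1)) / case_risks.size)
    if sens < target_sens - 1e-12:
        raise ValueError("no threshold attains the target sensitivity")
    return _summarise(flags, y, "B", threshold)


# ---------------------------------------------------------------------------
# Reclassification


def reclassification_table(ref_flags, model_flags, outcomes) -> dict:
    """Eight-cell cross-tabulation of two screens stratified by outcome.

    Keys: ``(outcome, reference, model)`` with outcome in {"gdm",
    "no_gdm"} and the screens in {"high", "low"}; plus derived deltas —
    additional cases flagged by the model and the reduction in non-cases
    flagged, relative to the reference method.
    """
    ref = np.asarray(ref_flags).astype(bool)
    mod = np.asarray(model_flags).astype(bool)
    y = np.asarray(outcomes).astype(bool)
    if not (len(ref) == len(mod) == len(y)):
        raise ValueError("ref_flags, model_flags and outcomes must have equal length")
    counts = {}
    for outcome_val, outcome_key in ((True, "gdm"), (False, "no_gdm")):
        for ref_val, ref_key in ((True, "high"), (False, "low")):
            for mod_val, mod_key in ((True, "high"), (False, "low")):
                counts[(outcome_key, ref_key, mod_key)] = int(
                    np.sum((y == outcome_val) & (ref == ref_val) & (mod == mod_val))
                )
    cases_gained = counts[("gdm", "low", "high")] - counts[("gdm", "high", "low")]
    noncases_spared = counts[("no_gdm", "high", "low")] - counts[("no_gdm", "low", "high")]
    return {
        "counts": counts,
        "additional_cases_flagged": cases_gained,
        "fewer_noncases_flagged": noncases_spared,
    }


def reclassification_json(table: dict) -> dict:
    """JSON-serialisable form of a reclassification table."""
    return {
        "counts": {
            f"{o}|ref_{r}|model_{m}": v for (o, r, m), v in table["counts"].items()
        },
        "additional_cases_flagged": table["additional_cases_flagged"],
        "fewer_noncases_flagged": table["fewer_noncases_flagged"],
    }
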