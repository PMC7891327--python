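"""End-to-end screening comparison: simulate/load -> impute -> update ->
evaluate -> compare.

The front door is :class:`ScreeningComparison`, a Model/Results pair in
the statsmodels idiom: construct it from an imputed (or complete) cohort
plus the model config, call :meth:`~ScreeningComparison.fit`, and read
everything — pooled c-statistics, updating coefficients, likelihood-ratio
tests, decision curves, scenario comparisons — off the returned
:class:`ScreeningComparisonResults`, whose ``summary()`` prints the
before/after-glucose discrimination table alongside the reference method.

:func:`run_analysis` wraps the whole thing behind an
:class:`AnalysisConfig` (YAML-friendly), writes a machine-readable report
and is bit-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import OUTCOME, read_cohort_csv, write_cohort_csv
from .decision import (
    DEFAULT_THRESHOLD_GRID,
    DecisionCurve,
    decision_curve,
    reclassification_json,
    reclassification_table,
    scenario_fixed_fraction,
    scenario_fixed_sensitivity,
)
from .impute import ImputedSet, PooledEstimate, impute, rubin_pool, write_imputed
from .metrics import (
    calibration_points_frame,
    classification_measures,
    pooled_c_statistic,
    stacked_calibration,
)
from .models import (
    ModelSpec,
    ReferenceMethodConfig,
    load_model_config,
    reference_classify,
)
from .simulate import (
    GeneratorConfig,
    MissingnessConfig,
    apply_missingness,
    default_missingness,
    generate_cohort,
    generator_config_from_yaml,
    missingness_config_from_yaml,
)
from .updating import PooledUpdatedModel, fit_updated_models

logger = logging.getLogger("gdmscreen")


# ---------------------------------------------------------------------------
# Results containers


@dataclass
class StrategyPerformance:
    """Pooled discrimination and classification for one strategy."""

    name: str
    c_statistic: PooledEstimate
    sensitivity: PooledEstimate | None = None
    specificity: PooledEstimate | None = None
    ppv: PooledEstimate | None = None
    npv: PooledEstimate | None = None
    flagged_fraction: float | None = None
    counts: dict | None = None


def _pool_proportions(values: list[float], ns: list[int]) -> PooledEstimate:
    variances = [p * (1 - p) / n if n > 0 else 0.0 for p, n in zip(values, ns)]
    return rubin_pool(values, variances, df_complete=min(ns) - 1 if ns else None)


@dataclass
class ScreeningComparisonResults:
    """Everything the comparison computes, pooled over imputations."""

    reference: StrategyPerformance
    updated_models: dict[str, PooledUpdatedModel]
    model_performance: dict[str, StrategyPerformance]  # keys: name/recal, name/ext
    m: int
    n: int
    prevalence: float
    threshold_grid: np.ndarray
    _imputed: ImputedSet = None  # type: ignore[assignment]
    _reference_config: ReferenceMethodConfig = None  # type: ignore[assignment]

    # -- convenience views ---------------------------------------------------

    def c_table(self) -> pd.DataFrame:
        """Discrimination table: c before/after glucose per model,
        reference method first."""
        rows = [
            {
                "strategy": "reference",
                "c_before": self.reference.c_statistic.qbar,
                "ci_before": (self.reference.c_statistic.ci_low,
                              self.reference.c_statistic.ci_high),
                "c_after": None,
                "ci_after": None,
                "lr_median_p": None,
            }
        ]
        for name, upd in self.updated_models.items():
            before = self.model_performance[f"{name}/recalibrated"].c_statistic
            after = self.model_performance[f"{name}/extended"].c_statistic
            rows.append(
                {
                    "strategy": name,
                    "c_before": before.qbar,
                    "ci_before": (before.ci_low, before.ci_high),
                    "c_after": after.qbar,
                    "ci_after": (after.ci_low, after.ci_high),
                    "lr_median_p": upd.lr_median_p,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable before/after-glucose discrimination table."""
        def fmt(est):
            if est is None or est[0] is None or pd.isna(est[0]):
                return "--"
            return f"{est[0]:.3f}"

        def fmt_ci(ci):
            if ci is None or not isinstance(ci, tuple) or ci[0] is None:
                return ""
            return f"({ci[0]:.3f}-{ci[1]:.3f})"

        lines = [
            f"First-trimester GDM screening comparison  (n={self.n}, m={self.m} "
            f"imputations, prevalence {100 * self.prevalence:.1f}%)",
            "",
            f"{'strategy':<22}{'c before':<10}{'95% CI':<16}"
            f"{'c after':<10}{'95% CI':<16}{'LR p (median)':<12}",
        ]
        for _, row in self.c_table().iterrows():
            lr = "" if pd.isna(row["lr_median_p"]) else f"{row['lr_median_p']:.3f}"
            lines.append(
                f"{row['strategy']:<22}{fmt((row['c_before'],)):<10}"
                f"{fmt_ci(row['ci_before']):<16}"
                f"{fmt((row['c_after'],)):<10}"
                f"{fmt_ci(row['ci_after']):<16}{lr:<12}"
            )
        ref = self.reference
        if ref.sensitivity is not None:
            lines += [
                "",
                "reference method operating point: "
                f"sensitivity {ref.sensitivity.qbar:.2f}, "
                f"specificity {ref.specificity.qbar:.2f}, "
                f"PPV {ref.ppv.qbar:.2f}, NPV {ref.npv.qbar:.2f}, "
                f"flagged {100 * ref.flagged_fraction:.1f}%",
            ]
        return "\n".join(lines)

    # -- risk functions (pooled coefficients, per completed table) -----------

    def _strategies(self, extended: bool | None = None) -> dict:
        out = {}
        for name, upd in self.updated_models.items():
            if extended is None or extended is False:
                out[f"{name}/recalibrated"] = upd.recalibrated_risk
            if extended is None or extended is True:
                out[f"{name}/extended"] = upd.extended_risk
        return out

    def decision_curve(self, grid=None, extended: bool | None = True) -> DecisionCurve:
        """Decision curves for the updated models (default: the
        glucose-extended versions), the reference method's fixed flags,
        treat-all and treat-none."""
        return decision_curve(
            self._strategies(extended),
            self._imputed,
            grid=grid if grid is not None else self.threshold_grid,
            reference_flags_fn=lambda t: reference_classify(t, self._reference_config),
        )

    def scenarios(
        self,
        target_fraction: float | None = None,
        target_sensitivity: float | None = None,
        extended: bool = True,
    ) -> dict:
        """Fixed-operating-point comparisons against the reference method.

        Targets default to the reference method's own pooled flagged
        fraction (scenario A) and sensitivity (scenario B) on this data.
        Metrics are computed per imputation and averaged; reclassification
        counts are averaged across imputations and rounded.
        """
        if target_fraction is None:
            target_fraction = self.reference.flagged_fraction
        if target_sensitivity is None:
            target_sensitivity = self.reference.sensitivity.qbar
        out = {}
        for name, risk_fn in self._strategies(extended).items():
            per_imp = {"A": [], "B": []}
            recls = {"A": [], "B": []}
            for table in self._imputed:
                y = table[OUTCOME].to_numpy(dtype=float)
                risks = np.asarray(risk_fn(table), dtype=float)
                ref_flags = reference_classify(table, self._reference_config)
                res_a = scenario_fixed_fraction(risks, y, target_fraction)
                res_b = scenario_fixed_sensitivity(risks, y, target_sensitivity)
                per_imp["A"].append(res_a)
                per_imp["B"].append(res_b)
                order = np.argsort(-risks, kind="stable")
                k = int(np.floor(target_fraction * len(risks) + 1e-12))
                flags_a = np.zeros(len(risks), dtype=bool)
                flags_a[order[:k]] = True
                flags_b = risks >= res_b.threshold
                recls["A"].append(reclassification_table(ref_flags, flags_a, y))
                recls["B"].append(reclassification_table(ref_flags, flags_b, y))
            out[name] = {
                scen: {
                    "threshold": float(np.mean([r.threshold for r in per_imp[scen]])),
                    "flagged_fraction": float(
                        np.mean([r.flagged_fraction for r in per_imp[scen]])
                    ),
                    "sensitivity": float(np.mean([r.sensitivity for r in per_imp[scen]])),
                    "specificity": float(np.mean([r.specificity for r in per_imp[scen]])),
                    "sensitivity_spread": [
                        float(np.min([r.sensitivity for r in per_imp[scen]])),
                        float(np.max([r.sensitivity for r in per_imp[scen]])),
                    ],
                    "reclassification": _average_reclassification(recls[scen]),
                }
                for scen in ("A", "B")
            }
        return out

    def calibration(self, strategy: str, n_bins: int = 10):
        """Stacked-imputation calibration points for one strategy key
        (``<model>/recalibrated`` or ``<model>/extended``)."""
        risk_fn = self._strategies()[strategy]
        return stacked_calibration(self._imputed, risk_fn, n_bins=n_bins)


def _average_reclassification(tables: list[dict]) -> dict:
    keys = tables[0]["counts"].keys()
    avg = {k: float(np.mean([t["counts"][k] for t in tables])) for k in keys}
    return {
        "counts": {f"{o}|ref_{r}|model_{m}": round(v, 1) for (o, r, m), v in avg.items()},
        "additional_cases_flagged": float(
            np.mean([t["additional_cases_flagged"] for t in tables])
        ),
        "fewer_noncases_flagged": float(
            np.mean([t["fewer_noncases_flagged"] for t in tables])
        ),
    }


# ---------------------------------------------------------------------------
# The Model side


class ScreeningComparison:
    """Compare rule-based selection with recalibrated prognostic models.

    Parameters
    ----------
    imputed
        An :class:`~gdmscreen.impute.ImputedSet` (use
        :meth:`from_cohort` to impute a raw cohort first).
    model_specs
        The published models to recalibrate and extend; defaults to the
        four shipped specs.
    reference_config
        The single-risk-factor rule settings.
    threshold_grid
        Decision-curve thresholds; default 0.005 to 0.30 step 0.005.
    """

    def __init__(
        self,
        imputed: ImputedSet,
        model_specs: list[ModelSpec] | None = None,
        reference_config: ReferenceMethodConfig | None = None,
        threshold_grid=None,
    ):
        if model_specs is None or reference_config is None:
            default_specs, default_ref = load_model_config()
            model_specs = model_specs or default_specs
            reference_config = reference_config or default_ref
        self.imputed = imputed
        self.model_specs = model_specs
        self.reference_config = reference_config
        self.threshold_grid = (
            np.asarray(threshold_grid, dtype=float)
            if threshold_grid is not None
            else DEFAULT_THRESHOLD_GRID
        )

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        m: int = 10,
        seed: int = 0,
        **kwargs,
    ) -> "ScreeningComparison":
        """Impute a (possibly incomplete) cohort, then build the model."""
        return cls(impute(cohort, m=m, seed=seed), **kwargs)

    def fit(self) -> ScreeningComparisonResults:
        imputed = self.imputed
        y = imputed.tables[0][OUTCOME].to_numpy(dtype=float)
        n = len(y)
        logger.info("fitting on n=%d subjects, m=%d imputations", n, imputed.m)

        # reference method: flags per imputation (BMI may be imputed)
        flags_per_imp = [
            np.asarray(reference_classify(t, self.reference_config)) for t in imputed
        ]
        ref_c = pooled_c_statistic([f.astype(float) for f in flags_per_imp], y)
        reports = [classification_measures(f, y) for f in flags_per_imp]
        ns_case = [r.tp + r.fn for r in reports]
        ns_ctrl = [r.tn + r.fp for r in reports]
        reference = StrategyPerformance(
            name="reference",
            c_statistic=ref_c,
            sensitivity=_pool_proportions(
                [r.sensitivity.value for r in reports], ns_case
            ),
            specificity=_pool_proportions(
                [r.specificity.value for r in reports], ns_ctrl
            ),
            ppv=_pool_proportions(
                [r.ppv.value for r in reports], [r.tp + r.fp for r in reports]
            ),
            npv=_pool_proportions(
                [r.npv.value for r in reports], [r.tn + r.fn for r in reports]
            ),
            flagged_fraction=float(np.mean([r.flagged_fraction for r in reports])),
            counts={
                "tp": float(np.mean([r.tp for r in reports])),
                "fp": float(np.mean([r.fp for r in reports])),
                "fn": float(np.mean([r.fn for r in reports])),
                "tn": float(np.mean([r.tn for r in reports])),
            },
        )
        logger.info(
            "reference method: flagged %.1f%%, pooled c %.3f",
            100 * reference.flagged_fraction, ref_c.qbar,
        )

        updated: dict[str, PooledUpdatedModel] = {}
        performance: dict[str, StrategyPerformance] = {}
        for spec in self.model_specs:
            upd = fit_updated_models(imputed, spec)
            updated[spec.name] = upd
            for label, risk_fn in (
                ("recalibrated", upd.recalibrated_risk),
                ("extended", upd.extended_risk),
            ):
                risks = [risk_fn(t) for t in imputed]
                performance[f"{spec.name}/{label}"] = StrategyPerformance(
                    name=f"{spec.name}/{label}",
                    c_statistic=pooled_c_statistic(risks, y),
                )
            logger.info(
                "%s: slope %.3f, c %.3f -> %.3f with glucose (median LR p %.3f)",
                spec.name,
                upd.calibration_slope.qbar,
                performance[f"{spec.name}/recalibrated"].c_statistic.qbar,
                performance[f"{spec.name}/extended"].c_statistic.qbar,
                upd.lr_median_p,
            )

        return ScreeningComparisonResults(
            reference=reference,
            updated_models=updated,
            model_performance=performance,
            m=imputed.m,
            n=n,
            prevalence=float(y.mean()),
            threshold_grid=self.threshold_grid,
            _imputed=imputed,
            _reference_config=self.reference_config,
        )


# ---------------------------------------------------------------------------
# Config-driven runner


@dataclass
class AnalysisConfig:
    """One full analysis run. Exactly one input source: a cohort CSV or a
    synthetic generator config (optionally with a missingness stage)."""

    cohort_csv: str | None = None
    generator: GeneratorConfig | None = None
    missingness: MissingnessConfig | None = None
    model_config: str | None = None  # YAML path; None -> shipped config
    m: int = 10
    seed: int = 0
    threshold_grid: tuple[float, float, float] = (0.005, 0.30, 0.005)  # start, stop, step
    # "from_reference" or explicit numbers
    scenario_fraction: float | str = "from_reference"
    scenario_sensitivity: float | str = "from_reference"
    output_dir: str = "gdmscreen_output"
    write_plots: bool = False

    def validate(self) -> None:
        if (self.cohort_csv is None) == (self.generator is None):
            raise ValueError("exactly one of cohort_csv or generator must be set")
        if self.m < 2:
            raise ValueError("m must be >= 2")
        start, stop, step = self.threshold_grid
        if not (0 < start <= stop < 1 and step > 0):
            raise ValueError("threshold_grid must satisfy 0 < start <= stop < 1, step > 0")


def _grid(cfg: AnalysisConfig) -> np.ndarray:
    start, stop, step = cfg.threshold_grid
    return np.round(np.arange(start, stop + step / 2, step), 9)


def _config_hash(cfg: AnalysisConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, frozenset):
            return sorted(o)
        return str(o)

    payload = dataclasses.asdict(cfg)
    # only analytic settings enter the hash, not where outputs land
    payload.pop("output_dir", None)
    payload.pop("write_plots", None)
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_analysis(config: AnalysisConfig) -> dict:
    """Execute the full pipeline and write all artifacts.

    Returns the report dict (also written as ``report.json``). Identical
    config and seed give identical outputs.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        cohort = generate_cohort(gen)
        logger.info("simulated cohort: n=%d, prevalence %.2f%%",
                    len(cohort), 100 * cohort[OUTCOME].mean())
        if config.missingness is not None:
            miss = dataclasses.replace(config.missingness, seed=config.seed + 1)
            cohort = apply_missingness(cohort, miss)
            n_missing = int(cohort.isna().sum().sum())
            logger.info("missingness applied: %d missing cells", n_missing)
        write_cohort_csv(cohort, out_dir / "cohort.csv")
    else:
        cohort = read_cohort_csv(config.cohort_csv)
        logger.info("loaded cohort %s: n=%d", config.cohort_csv, len(cohort))

    specs, ref_cfg = load_model_config(config.model_config)
    imputed = impute(cohort, m=config.m, seed=config.seed + 2)
    write_imputed(imputed, out_dir / "imputed.csv", out_dir / "imputed_meta.json")

    comparison = ScreeningComparison(
        imputed, model_specs=specs, reference_config=ref_cfg, threshold_grid=_grid(config)
    )
    results = comparison.fit()

    curve = results.decision_curve()
    curve.to_frame().to_csv(out_dir / "decision_curve.csv", index=False)

    tf = None if config.scenario_fraction == "from_reference" else float(config.scenario_fraction)
    ts = (
        None
        if config.scenario_sensitivity == "from_reference"
        else float(config.scenario_sensitivity)
    )
    scenarios = results.scenarios(target_fraction=tf, target_sensitivity=ts)

    calib_frames = []
    for key in results.model_performance:
        frame = calibration_points_frame(results.calibration(key))
        frame.insert(0, "strategy", key)
        calib_frames.append(frame)
    pd.concat(calib_frames, ignore_index=True).to_csv(
        out_dir / "calibration_points.csv", index=False
    )

    report = build_report(config, results, scenarios)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    if config.write_plots:
        _write_plots(results, curve, scenarios, out_dir)

    manifest = sorted(p.name for p in out_dir.iterdir() if p.is_file())
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump({"files": manifest}, fh, indent=2)
    return report


def _pe(est: PooledEstimate | None) -> dict | None:
    if est is None:
        return None
    return {
        "estimate": est.qbar,
        "W": est.W,
        "B": est.B,
        "T": est.T,
        "m": est.m,
        "ci": [est.ci_low, est.ci_high],
    }


def build_report(
    config: AnalysisConfig, results: ScreeningComparisonResults, scenarios: dict
) -> dict:
    ref = results.reference
    report = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "m": results.m,
            "n": results.n,
            "config_hash": _config_hash(config),
        },
        "prevalence": results.prevalence,
        "reference": {
            "c_statistic": _pe(ref.c_statistic),
            "sensitivity": _pe(ref.sensitivity),
            "specificity": _pe(ref.specificity),
            "ppv": _pe(ref.ppv),
            "npv": _pe(ref.npv),
            "flagged_fraction": ref.flagged_fraction,
            "counts": ref.counts,
        },
        "models": {},
        "scenarios": scenarios,
    }
    for name, upd in results.updated_models.items():
        report["models"][name] = {
            "recalibration": {
                "intercept": _pe(upd.calibration_intercept),
                "slope": _pe(upd.calibration_slope),
            },
            "extension": {
                "intercept": _pe(upd.ext_intercept),
                "lp_coefficient": _pe(upd.ext_lp_coefficient),
                "glucose_coefficient": _pe(upd.ext_glucose_coefficient),
            },
            "lr_test": {
                "per_imputation_chi_square": [t.chi_square for t in upd.lr_per_imputation],
                "per_imputation_p": [t.p_value for t in upd.lr_per_imputation],
                "median_chi_square": upd.lr_median_chi_square,
                "median_p": upd.lr_median_p,
                "fraction_significant_0.05": upd.lr_fraction_significant,
            },
            "c_statistic": {
                "recalibrated": _pe(
                    results.model_performance[f"{name}/recalibrated"].c_statistic
                ),
                "extended": _pe(
                    results.model_performance[f"{name}/extended"].c_statistic
                ),
            },
        }
    return report


def _write_plots(results, curve, scenarios, out_dir: Path) -> None:
    from .metrics import calibration_smooth
    from .plots import plot_calibration, plot_decision_curves, save_figure

    save_figure(
        plot_decision_curves(curve, title="Decision curve analysis"),
        out_dir / "decision_curves.png",
    )
    for key in results.model_performance:
        points = results.calibration(key)
        safe = key.replace("/", "_")
        save_figure(
            plot_calibration(points, title=key),
            out_dir / f"calibration_{safe}.png",
        )
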