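"""Declarative logistic risk equations and the single-risk-factor rule.

The four published first-trimester prognostic models for gestational
diabetes (Gabbay-Benziv 2014, Nanda 2011, Teede 2011, van Leeuwen 2010) are
represented declaratively: an intercept plus terms of the form
``coefficient * transform(predictor)``, where a transform is the identity,
the natural log, or a category indicator. Risk is the inverse logit of the
linear predictor. Coefficients are never hard-coded — they are loaded from
a YAML config (see :func:`load_model_config`) whose schema validator
enforces each named model's published predictor set.

The reference method ("single risk factor approach") is the care-as-usual
rule: a woman is high-risk if at least one of five factors is present —
BMI above a cut-off, a previous macrosomic child, a history of gestational
diabetes, a first-degree family history of diabetes, or an ethnicity in a
configured non-western high-prevalence set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CATEGORY_LEVELS, ETHNICITY_LEVELS, SCHEMA

TRANSFORMS = ("identity", "natural_log", "indicator")

#: published predictor sets; a named model's config must use exactly these
PUBLISHED_PREDICTOR_SETS: dict[str, frozenset[str]] = {
    "gabbay_benziv_2014": frozenset(
        {"age_years", "bmi", "ethnicity", "history_gdm", "sbp_mmhg"}
    ),
    "nanda_2011": frozenset(
        {"age_years", "bmi", "ethnicity", "history_gdm", "parity", "history_macrosomia"}
    ),
    "teede_2011": frozenset(
        {"age_years", "bmi", "ethnicity", "history_gdm", "family_history_dm"}
    ),
    "van_leeuwen_2010": frozenset(
        {"bmi", "ethnicity", "history_gdm", "family_history_dm", "parity"}
    ),
}


class ModelConfigError(ValueError):
    """A model config file violates the schema or a predictor-set rule."""


class MissingPredictorError(ValueError):
    """A subject lacks a predictor the model requires (impute first)."""


@dataclass(frozen=True)
class Term:
    """One additive term of a logistic risk equation."""

    predictor: str
    transform: str = "identity"
    coefficient: float = 0.0
    level: str | None = None  # only for transform == "indicator"

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ModelConfigError(
                f"unknown transform {self.transform!r} for predictor {self.predictor!r}"
            )
        if self.predictor not in SCHEMA:
            raise ModelConfigError(f"unknown predictor {self.predictor!r}")
        if self.transform == "indicator":
            levels = CATEGORY_LEVELS.get(self.predictor)
            if levels is None:
                raise ModelConfigError(
                    f"indicator transform needs a categorical predictor, got {self.predictor!r}"
                )
            if self.level not in levels:
                raise ModelConfigError(
                    f"level {self.level!r} not valid for {self.predictor!r}; allowed {levels}"
                )
        elif self.level is not None:
            raise ModelConfigError(
                f"level given for non-indicator term on {self.predictor!r}"
            )


@dataclass(frozen=True)
class ModelSpec:
    """A logistic risk equation: ``logit(risk) = intercept + sum(terms)``."""

    name: str
    intercept: float
    terms: tuple[Term, ...] = ()

    def __post_init__(self) -> None:
        published = PUBLISHED_PREDICTOR_SETS.get(self.name)
        if published is not None:
            used = {t.predictor for t in self.terms}
            if used != published:
                extra = sorted(used - published)
                absent = sorted(published - used)
                raise ModelConfigError(
                    f"model {self.name!r} predictor set mismatch: "
                    f"unexpected {extra}, missing {absent}"
                )

    @property
    def predictors(self) -> frozenset[str]:
        return frozenset(t.predictor for t in self.terms)

    def linear_predictor(self, table: pd.DataFrame | pd.Series) -> np.ndarray | float:
        """Evaluate the linear predictor for a subject or a cohort.

        Raises :class:`MissingPredictorError` if any required predictor is
        missing for any scored row — scoring must follow imputation.
        """
        if isinstance(table, pd.Series):
            return float(self.linear_predictor(table.to_frame().T)[0])
        lp = np.full(len(table), self.intercept, dtype=float)
        for term in self.terms:
            col = table[term.predictor] if term.predictor in table else None
            if col is None:
                raise MissingPredictorError(
                    f"predictor {term.predictor!r} absent from cohort"
                )
            if col.isna().any():
                raise MissingPredictorError(
                    f"predictor {term.predictor!r} has missing values; impute before scoring"
                )
            if term.transform == "identity":
                x = col.to_numpy(dtype=float)
            elif term.transform == "natural_log":
                vals = col.to_numpy(dtype=float)
                if (vals <= 0).any():
                    raise ValueError(
                        f"natural_log transform of {term.predictor!r} requires positive values"
                    )
                x = np.log(vals)
            else:  # indicator
                x = (col.to_numpy() == term.level).astype(float)
            lp += term.coefficient * x
        return lp

    def predicted_risk(self, table: pd.DataFrame | pd.Series) -> np.ndarray | float:
        return predicted_risk(self.linear_predictor(table))


def predicted_risk(lp):
    """Inverse logit ``1 / (1 + exp(-lp))``; strictly increasing in lp."""
    lp = np.asarray(lp, dtype=float)
    out = np.empty_like(lp)
    pos = lp >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-lp[pos]))
    e = np.exp(lp[~pos])
    out[~pos] = e / (1.0 + e)
    if out.ndim == 0:
        return float(out)
    return out


def logit(p):
    p = np.asarray(p, dtype=float)
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ReferenceMethodConfig:
    """Configuration of the single-risk-factor rule.

    The BMI cut-off is strict (``bmi > cutoff``) following the Methods
    description of the Dutch guideline rule; the abstract prints the
    non-strict form, so the comparison is configurable. The non-western
    high-prevalence ethnicity set defaults to {asian, other}: the
    guideline's list (Hindustani, Moroccan, Turkish, Middle Eastern,
    Asian) does not map one-to-one onto the cohort's five categories.
    """

    bmi_cutoff: float = 30.0
    bmi_strict: bool = True
    high_prevalence_ethnicities: frozenset[str] = frozenset({"asian", "other"})

    def __post_init__(self) -> None:
        bad = set(self.high_prevalence_ethnicities) - set(ETHNICITY_LEVELS)
        if bad:
            raise ModelConfigError(f"unknown ethnicities in reference config: {sorted(bad)}")


REFERENCE_RULE_FIELDS = (
    "bmi",
    "history_macrosomia",
    "history_gdm",
    "family_history_dm",
    "ethnicity",
)


def reference_classify(
    table: pd.DataFrame | pd.Series,
    config: ReferenceMethodConfig | None = None,
) -> np.ndarray | bool:
    """Apply the single-risk-factor rule; True means high-risk.

    High-risk iff at least one rule fires: BMI above the cut-off, history
    of macrosomia, history of GDM, first-degree family history of any
    diabetes, or ethnicity in the high-prevalence set.
    """
    config = config or ReferenceMethodConfig()
    if isinstance(table, pd.Series):
        return bool(reference_classify(table.to_frame().T, config)[0])
    for col in REFERENCE_RULE_FIELDS:
        if col not in table:
            raise MissingPredictorError(f"reference rule field {col!r} absent")
        if table[col].isna().any():
            raise MissingPredictorError(
                f"reference rule field {col!r} has missing values; impute before classifying"
            )
    bmi = table["bmi"].to_numpy(dtype=float)
    if config.bmi_strict:
        bmi_flag = bmi > config.bmi_cutoff
    else:
        bmi_flag = bmi >= config.bmi_cutoff
    flags = (
        bmi_flag
        | (table["history_macrosomia"].to_numpy() == 1)
        | (table["history_gdm"].to_numpy() == 1)
        | (table["family_history_dm"].to_numpy() == 1)
        | table["ethnicity"].isin(config.high_prevalence_ethnicities).to_numpy()
    )
    return flags


# ---------------------------------------------------------------------------
# YAML config loading

DEFAULT_MODEL_CONFIG = Path(__file__).parent / "data" / "published_models_synthetic.yaml"


def _parse_term(raw: dict, path: str) -> Term:
    if not isinstance(raw, dict):
        raise ModelConfigError(f"{path}: term must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - {"predictor", "transform", "coefficient", "level"}
    if unknown:
        raise ModelConfigError(f"{path}: unknown term keys {sorted(unknown)}")
    try:
        return Term(
            predictor=raw["predictor"],
            transform=raw.get("transform", "identity"),
            coefficient=float(raw["coefficient"]),
            level=raw.get("level"),
        )
    except KeyError as err:
        raise ModelConfigError(f"{path}: missing required key {err}") from err


def load_model_config(
    path: str | Path | None = None,
) -> tuple[list[ModelSpec], ReferenceMethodConfig]:
    """Load model specs and the reference-method rule from a YAML file.

    The file has the shape::

        models:
          - name: teede_2011
            intercept: -7.1
            terms:
              - {predictor: age_years, transform: identity, coefficient: 0.05}
              - {predictor: ethnicity, transform: indicator, level: asian, coefficient: 1.0}
        reference_method:
          bmi_cutoff: 30.0
          bmi_strict: true
          high_prevalence_ethnicities: [asian, other]

    Named published models are checked against their predictor sets; any
    violation raises :class:`ModelConfigError` with the offending field.
    """
    path = Path(path) if path is not None else DEFAULT_MODEL_CONFIG
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "models" not in raw:
        raise ModelConfigError(f"{path}: top level must be a mapping with a 'models' list")
    specs: list[ModelSpec] = []
    for i, m in enumerate(raw["models"]):
        where = f"{path}:models[{i}]"
        if not isinstance(m, dict):
            raise ModelConfigError(f"{where}: model entry must be a mapping")
        unknown = set(m) - {"name", "intercept", "terms"}
        if unknown:
            raise ModelConfigError(f"{where}: unknown keys {sorted(unknown)}")
        try:
            name = m["name"]
            intercept = float(m["intercept"])
        except KeyError as err:
            raise ModelConfigError(f"{where}: missing required key {err}") from err
        terms = tuple(
            _parse_term(t, f"{where}.terms[{j}]") for j, t in enumerate(m.get("terms", []))
        )
        specs.append(ModelSpec(name=name, intercept=intercept, terms=terms))

    ref_raw = raw.get("reference_method", {}) or {}
    unknown = set(ref_raw) - {"bmi_cutoff", "bmi_strict", "high_prevalence_ethnicities"}
    if unknown:
        raise ModelConfigError(f"{path}:reference_method: unknown keys {sorted(unknown)}")
    ref = ReferenceMethodConfig(
        bmi_cutoff=float(ref_raw.get("bmi_cutoff", 30.0)),
        bmi_strict=bool(ref_raw.get("bmi_strict", True)),
        high_prevalence_ethnicities=frozenset(
            ref_raw.get("high_prevalence_ethnicities", ("asian", "other"))
        ),
    )
    return specs, ref


def intercept_only(value: float, name: str = "custom") -> ModelSpec:
    """Convenience: an intercept-only equation (constant risk)."""
    return ModelSpec(name=name, intercept=float(value))
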