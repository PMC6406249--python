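"""Cohort transfer and survival analysis: per-cohort z-scoring, three-group
classification, Kaplan-Meier / log-rank, Cox proportional hazards, and
Schoenfeld sample-size planning.

Kaplan-Meier, log-rank and Cox fits are delegated to ``lifelines``; this
module owns the cohort container, the per-cohort standardization used to
transfer a panel across expression platforms, the Table-style covariate
codings, and the closed-form Schoenfeld events formula.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import norm

from .discovery import GROUP_LABELS, TrainedPanelModel

logger = logging.getLogger("chemopanel.validation")

__all__ = [
    "SurvivalCohort",
    "KMCurve",
    "SurvivalComparison",
    "CoxResult",
    "filter_cohort",
    "classify_cohort",
    "km_curve",
    "logrank_test",
    "compare_survival",
    "cox_fit",
    "schoenfeld_sample_size",
]

#: Clinical covariates in the standard coding (binary unless noted).
CLINICAL_COVARIATES = ("residual_tumor_lt_1cm", "figo_advanced", "grade_high", "histology")
HISTOLOGY_REFERENCE = "serous"


@dataclass(frozen=True)
class SurvivalCohort:
    """Per-patient panel expression plus time-to-event and clinical covariates.

    ``expression`` is genes × patients; ``clinical`` is indexed by patient id
    with at least ``time`` (≥ 0) and ``event`` (0/1) columns, optionally a
    ``treated`` flag and the standard covariates. ``endpoint`` tags the
    outcome (OS or RFS); ``time_unit`` declares days or months.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    endpoint: str = "OS"
    time_unit: str = "days"

    def __post_init__(self) -> None:
        if self.clinical.index.has_duplicates:
            raise ValueError("duplicate patient ids in clinical table")
        for col in ("time", "event"):
            if col not in self.clinical.columns:
                raise ValueError(f"clinical table lacks required column {col!r}")
        times = self.clinical["time"].to_numpy(dtype=float)
        if (times < 0).any() or not np.isfinite(times).all():
            raise ValueError("survival times must be finite and >= 0")
        events = self.clinical["event"].to_numpy()
        if not np.isin(events, [0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        missing = [p for p in self.clinical.index if p not in self.expression.columns]
        if missing:
            raise ValueError(f"patients lacking expression: {missing[:10]}")

    @property
    def patient_ids(self) -> list:
        return list(self.clinical.index)

    @property
    def n_patients(self) -> int:
        return len(self.clinical)


def filter_cohort(
    cohort: SurvivalCohort,
    min_survival_days: int = 30,
    require_chemo: bool = True,
) -> SurvivalCohort:
    """Restrict to treated patients surviving strictly longer than the minimum.

    A patient whose survival time equals ``min_survival_days`` exactly is
    excluded (the rule is "longer than", not "at least").
    """
    keep = cohort.clinical["time"] > min_survival_days
    if require_chemo:
        if "treated" not in cohort.clinical.columns:
            raise ValueError("cohort has no 'treated' column but require_chemo is set")
        keep &= cohort.clinical["treated"].astype(bool)
    kept = cohort.clinical.index[keep]
    logger.info("filter_cohort: %d -> %d patients (min_survival>%d, require_chemo=%s)",
                cohort.n_patients, len(kept), min_survival_days, require_chemo)
    if len(kept) == 0:
        raise ValueError("no patients remain after filtering")
    return dc_replace(
        cohort,
        expression=cohort.expression[kept],
        clinical=cohort.clinical.loc[kept],
    )


def classify_cohort(
    model: TrainedPanelModel,
    cohort: SurvivalCohort,
    standardize: str = "cohort",
) -> pd.Series:
    """Predict low/medium/high response for every patient in the cohort.

    By default (``standardize='cohort'``) each panel gene is z-scored across
    this cohort's own patients before prediction, which removes platform
    scale and location differences; ``standardize='training'`` applies the
    panel's training mean/sd instead.
    """
    missing = [g for g in model.panel.genes if g not in cohort.expression.index]
    if missing:
        raise KeyError(f"panel genes missing from cohort expression: {missing}")
    feats = cohort.expression.loc[list(model.panel.genes), cohort.patient_ids].T
    if standardize == "cohort":
        sds = feats.std(axis=0, ddof=1)
        constant = sds[sds == 0].index.tolist()
        if constant:
            raise ValueError(f"panel genes constant across the cohort: {constant}")
        feats = (feats - feats.mean(axis=0)) / sds
    elif standardize == "training":
        feats = model.standardize(feats)
    else:
        raise ValueError("standardize must be 'cohort' or 'training'")
    return model.predict(feats)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate: step function with at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function (S(0⁻) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate. S starts at 1 and drops at event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("survival times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return KMCurve(
        times=surv.index.to_numpy(dtype=float),
        survival=surv.to_numpy(dtype=float),
        at_risk=table["at_risk"].reindex(surv.index).to_numpy(dtype=float),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple:
    """Two-sided log-rank comparison of two groups (chi-square, 1 df)."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    for name, t in (("A", times_a), ("B", times_b)):
        if (t == 0).all():
            raise ValueError(f"group {name} has all survival times zero")
    res = _ll_logrank(times_a, times_b, event_observed_A=np.asarray(events_a, dtype=int),
                      event_observed_B=np.asarray(events_b, dtype=int))
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class SurvivalComparison:
    """Two-group survival contrast: log-rank test, KM curves and Cox hazard ratio."""

    group_a: str
    group_b: str
    statistic: float
    p_value: float
    curves: dict
    hazard_ratio: float
    hr_ci: tuple


def compare_survival(cohort: SurvivalCohort, labels: pd.Series,
                     group_a: str = "high", group_b: str = "low") -> SurvivalComparison:
    """Log-rank + KM + hazard ratio (A vs B) for two predicted response groups."""
    clin = cohort.clinical
    ids_a = labels.index[labels == group_a]
    ids_b = labels.index[labels == group_b]
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError(f"empty group: {group_a}={len(ids_a)}, {group_b}={len(ids_b)}")
    ta, ea = clin.loc[ids_a, "time"], clin.loc[ids_a, "event"]
    tb, eb = clin.loc[ids_b, "time"], clin.loc[ids_b, "event"]
    stat, p = logrank_test(ta, ea, tb, eb)
    curves = {group_a: km_curve(ta, ea), group_b: km_curve(tb, eb)}
    df = pd.DataFrame({
        "time": pd.concat([ta, tb]).to_numpy(),
        "event": pd.concat([ea, eb]).to_numpy(),
        "is_a": np.r_[np.ones(len(ids_a)), np.zeros(len(ids_b))],
    })
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["is_a"]))
    ci = cph.confidence_intervals_.loc["is_a"]
    return SurvivalComparison(
        group_a=group_a, group_b=group_b, statistic=stat, p_value=p, curves=curves,
        hazard_ratio=hr, hr_ci=(float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1]))),
    )


@dataclass(frozen=True)
class CoxResult:
    """Hazard ratios with Wald 95% CIs and p-values, per covariate."""

    model_type: str  # "univariate" | "multivariate"
    table: pd.DataFrame  # index covariate; columns hazard_ratio, ci_lower, ci_upper, p_value

    def __post_init__(self) -> None:
        t = self.table
        bad = (t["ci_lower"] <= 0) | (t["ci_lower"] > t["hazard_ratio"]) \
            | (t["hazard_ratio"] > t["ci_upper"])
        if bad.any():
            raise ValueError(f"inconsistent CI bounds for {list(t.index[bad])}")


def _model_term(labels: pd.Series, coding: str) -> pd.Series:
    """Covariate coding for the panel prediction: responders (=1) vs low (=0)."""
    if coding == "medium_high_vs_low":
        return (labels != "low").astype(float)
    if coding == "high_vs_low":
        sub = labels[labels.isin(["high", "low"])]
        return (sub == "high").astype(float)
    raise ValueError("coding must be 'medium_high_vs_low' or 'high_vs_low'")


def _covariate_frame(cohort: SurvivalCohort, covariates, labels, model_coding) -> pd.DataFrame:
    clin = cohort.clinical
    cols = {}
    for cov in covariates:
        if cov == "panel_model":
            if labels is None:
                raise ValueError("panel_model covariate requires predicted labels")
            cols["panel_model"] = _model_term(labels, model_coding)
        elif cov == "histology":
            hist = clin["histology"].astype(str)
            levels = [lv for lv in hist.unique() if lv != HISTOLOGY_REFERENCE]
            if not levels:
                logger.warning("cox_fit: histology has only the reference level; dropped")
            for lv in sorted(levels):
                ind = (hist == lv).astype(float)
                if ind.nunique() < 2:
                    logger.warning("cox_fit: histology level %r absent/constant; dropped", lv)
                    continue
                cols[f"histology_{lv}"] = ind
        else:
            if cov not in clin.columns:
                raise KeyError(f"covariate {cov!r} not in clinical table")
            v = clin[cov].astype(float)
            if v.nunique() < 2:
                raise ValueError(f"covariate {cov!r} has a single level")
            cols[cov] = v
    frame = pd.DataFrame(cols)
    # align on the patients present for every term (high_vs_low drops medium)
    frame = frame.dropna()
    frame.insert(0, "time", clin.loc[frame.index, "time"])
    frame.insert(1, "event", clin.loc[frame.index, "event"])
    return frame


def cox_fit(
    cohort: SurvivalCohort,
    covariates,
    model_type: str = "univariate",
    labels: pd.Series | None = None,
    model_coding: str = "medium_high_vs_low",
) -> CoxResult:
    """Cox proportional-hazards regression with the standard covariate codings.

    ``covariates`` may include the special name ``panel_model`` (the panel's
    predicted response, coded medium+high vs low by default, or high vs low
    with ``model_coding='high_vs_low'``), ``histology`` (categorical, serous
    reference, expanded to indicators) and any binary/numeric clinical column.
    Univariate fits each covariate alone; multivariate fits all jointly.
    Ties are handled with the Efron approximation.
    """
    if model_type not in ("univariate", "multivariate"):
        raise ValueError("model_type must be 'univariate' or 'multivariate'")
    if cohort.clinical["event"].sum() == 0:
        raise ValueError("no events in cohort; Cox model is not identifiable")
    frame = _covariate_frame(cohort, covariates, labels, model_coding)
    terms = [c for c in frame.columns if c not in ("time", "event")]

    def _fit(cols) -> pd.DataFrame:
        cph = CoxPHFitter()
        try:
            cph.fit(frame[["time", "event"] + cols], duration_col="time", event_col="event")
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            raise RuntimeError(
                f"Cox fit failed for {cols} (separation or collinearity?): {exc}"
            ) from exc
        s = cph.summary
        out = pd.DataFrame({
            "hazard_ratio": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p_value": s["p"],
        })
        return out

    if model_type == "univariate":
        parts = [_fit([t]) for t in terms]
        table = pd.concat(parts)
    else:
        table = _fit(terms)
    return CoxResult(model_type=model_type, table=table)


def schoenfeld_sample_size(
    hazard_ratio: float,
    alpha: float = 0.05,
    power: float = 0.70,
    event_probability: float = 1.0,
    group_proportion: float = 0.5,
) -> int:
    """Total sample size for a two-group log-rank comparison (Schoenfeld events formula).

    Required events E = (z_{1−α/2} + z_{power})² / (p(1−p)·(ln HR)²), where p
    is the proportion allocated to one group; the total n is E divided by the
    overall event probability, rounded up.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if hazard_ratio == 1:
        raise ValueError("hazard_ratio of 1 implies an infinite sample size")
    for name, v in (("alpha", alpha), ("power", power),
                    ("event_probability", event_probability),
                    ("group_proportion", group_proportion)):
        if not 0 < v <= 1:
            raise ValueError(f"{name} must be in (0, 1]")
    z = norm.ppf(1 - alpha / 2) + norm.ppf(power)
    events = z ** 2 / (group_proportion * (1 - group_proportion) * math.log(hazard_ratio) ** 2)
    return math.ceil(events / event_probability)
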