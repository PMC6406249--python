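"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators: a cell-line screen (expression matrix + continuous activity
area, with a handful of planted response-associated genes among noise) and a
patient cohort whose hazard depends on the panel-predicted response group.
Both are pure functions of their spec (seed included), so re-runs are
byte-identical. Expression noise is Gaussian and survival is exponential —
the simplest models consistent with the pipeline's rank-based and
proportional-hazards assumptions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discovery import (
    GROUP_LABELS,
    DrugResponseTable,
    ResponseGroups,
    TrainedPanelModel,
    assign_response_groups,
)
from .preprocess import ExpressionMatrix
from .validation import SurvivalCohort

logger = logging.getLogger("chemopanel.synthetic_data")

__all__ = [
    "CellLineSimSpec",
    "CohortSimSpec",
    "gen_cell_line_dataset",
    "gen_cohort",
]

#: Group shift multipliers for planted signal genes (low, medium, high).
_GROUP_SHIFT = {"low": -1.0, "medium": 0.0, "high": 1.0}


@dataclass(frozen=True)
class CellLineSimSpec:
    """Settings for the simulated cell-line screen.

    ``effect_size`` is the class-mean shift of planted genes between adjacent
    response groups, in units of ``noise_sd``. Activity areas are drawn
    uniformly on a continuous range, so the tertile split is almost surely
    tie-free. Baseline intensities are positive, keeping the probe-collapse
    coefficient of variation well defined.
    """

    n_cell_lines: int = 25
    n_genes: int = 2000
    n_signal_genes: int = 10
    effect_size: float = 3.0
    noise_sd: float = 1.0
    baseline_range: tuple = (5.0, 9.0)
    activity_range: tuple = (2.0, 7.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes must be <= n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_cell_lines < 3:
            raise ValueError("need at least 3 cell lines for tertile grouping")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def gen_cell_line_dataset(spec: CellLineSimSpec):
    """Simulate a cell-line expression matrix with a continuous drug phenotype.

    Signal genes get group-dependent mean shifts (−e, 0, +e · noise_sd for
    low/medium/high); noise genes are independent of the response.

    Returns
    -------
    (matrix, responses, signal_genes, true_groups)
        ExpressionMatrix (genes × cell lines), DrugResponseTable, the planted
        gene ids, and the ResponseGroups implied by the tertile rule.
    """
    rng = np.random.default_rng(spec.rng_seed)
    samples = [f"CL{i + 1:03d}" for i in range(spec.n_cell_lines)]
    genes = [f"G{i + 1:05d}" for i in range(spec.n_genes)]

    activity = rng.uniform(*spec.activity_range, size=spec.n_cell_lines)
    responses = DrugResponseTable(pd.Series(activity, index=samples, name="activity_area"))
    groups = assign_response_groups(responses)

    baseline = rng.uniform(*spec.baseline_range, size=spec.n_genes)
    values = baseline[:, None] + rng.normal(0.0, spec.noise_sd,
                                            size=(spec.n_genes, spec.n_cell_lines))
    signal_idx = rng.choice(spec.n_genes, size=spec.n_signal_genes, replace=False)
    shifts = np.array([_GROUP_SHIFT[groups.labels[s]] for s in samples])
    values[signal_idx] += spec.effect_size * spec.noise_sd * shifts[None, :]

    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    signal_genes = [genes[i] for i in sorted(signal_idx)]
    logger.info("gen_cell_line_dataset: %d genes x %d lines, %d planted (effect %.2g sd)",
                spec.n_genes, spec.n_cell_lines, spec.n_signal_genes, spec.effect_size)
    return matrix, responses, signal_genes, groups


@dataclass(frozen=True)
class CohortSimSpec:
    """Settings for a simulated validation cohort.

    Patient response groups are drawn with ``group_proportions`` (high
    responders a minority by default). Survival is exponential with
    group-specific hazards: either ``group_hazards`` directly, or derived
    from ``hazard_ratio`` (high vs low; medium takes the geometric mean).
    Censoring is independent exponential, tuned so the expected censored
    fraction equals ``censoring_rate``. Panel expression is drawn from the
    model's group-conditional training distributions, with the between-group
    separation scaled by ``expression_effect``.
    """

    n_patients: int = 300
    hazard_ratio: float = 0.52
    baseline_hazard: float = 0.002  # per day for the low group
    group_hazards: dict | None = None
    censoring_rate: float = 0.3
    expression_effect: float = 1.0
    group_proportions: dict = field(
        default_factory=lambda: {"low": 0.60, "medium": 0.25, "high": 0.15}
    )
    confound_covariates: bool = False
    endpoint: str = "OS"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.group_hazards is not None:
            if set(self.group_hazards) != set(GROUP_LABELS):
                raise ValueError("group_hazards must give a hazard for each group")
            if any(h <= 0 for h in self.group_hazards.values()):
                raise ValueError("hazards must be positive")
        props = self.group_proportions
        if set(props) != set(GROUP_LABELS) or abs(sum(props.values()) - 1) > 1e-9:
            raise ValueError("group_proportions must cover low/medium/high and sum to 1")

    def hazards(self) -> dict:
        if self.group_hazards is not None:
            return dict(self.group_hazards)
        b = self.baseline_hazard
        return {"low": b, "medium": b * self.hazard_ratio ** 0.5,
                "high": b * self.hazard_ratio}


_HISTOLOGY_LEVELS = ("serous", "endometrioid", "clear_cell", "mucinous")
_HISTOLOGY_PROBS = (0.70, 0.15, 0.10, 0.05)


def gen_cohort(spec: CohortSimSpec, model: TrainedPanelModel):
    """Simulate a patient cohort whose hazard follows the panel response group.

    Returns
    -------
    (cohort, true_groups) : (SurvivalCohort, pandas.Series)
        The cohort and the generating group label per patient.
    """
    rng = np.random.default_rng(spec.rng_seed)
    patients = [f"PT{i + 1:04d}" for i in range(spec.n_patients)]
    labels = np.array(GROUP_LABELS, dtype=object)
    probs = np.array([spec.group_proportions[g] for g in GROUP_LABELS])
    true_groups = pd.Series(rng.choice(labels, size=spec.n_patients, p=probs),
                            index=patients, name="true_group")

    # group-conditional expression from the model's standardized training data
    train = pd.DataFrame(model.training_features, columns=list(model.panel.genes))
    train_y = pd.Series(model.training_labels)
    overall = train.mean(axis=0)
    expr = np.empty((len(model.panel.genes), spec.n_patients))
    for g in GROUP_LABELS:
        mask = (true_groups == g).to_numpy()
        if not mask.any():
            continue
        gm = train[train_y.to_numpy() == g].mean(axis=0)
        gs = train[train_y.to_numpy() == g].std(axis=0, ddof=1).fillna(1.0).replace(0.0, 1.0)
        centered = overall + spec.expression_effect * (gm - overall)
        expr[:, mask] = (
            centered.to_numpy()[:, None]
            + gs.to_numpy()[:, None] * rng.normal(size=(len(gm), int(mask.sum())))
        )
    expression = pd.DataFrame(expr, index=list(model.panel.genes), columns=patients)

    hazards = spec.hazards()
    h = np.array([hazards[g] for g in true_groups])
    event_times = rng.exponential(1.0 / h)
    if spec.censoring_rate > 0:
        # exponential censoring with P(censor before event) = censoring_rate
        c = h * spec.censoring_rate / (1.0 - spec.censoring_rate)
        censor_times = rng.exponential(1.0 / c)
        time = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    else:
        time, event = event_times, np.ones(spec.n_patients, dtype=int)

    if spec.confound_covariates:
        # better-debulked patients enriched among high responders
        p_resid = np.where(true_groups == "high", 0.75,
                           np.where(true_groups == "medium", 0.55, 0.40))
    else:
        p_resid = np.full(spec.n_patients, 0.5)
    clinical = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "treated": np.ones(spec.n_patients, dtype=int),
            "residual_tumor_lt_1cm": rng.binomial(1, p_resid),
            "figo_advanced": rng.binomial(1, 0.8, size=spec.n_patients),
            "grade_high": rng.binomial(1, 0.6, size=spec.n_patients),
            "histology": rng.choice(np.array(_HISTOLOGY_LEVELS, dtype=object),
                                    size=spec.n_patients, p=_HISTOLOGY_PROBS),
        },
        index=patients,
    )
    cohort = SurvivalCohort(expression=expression, clinical=clinical,
                            endpoint=spec.endpoint, time_unit="days")
    logger.info("gen_cohort: %d patients, hazards=%s, censoring=%.0f%%",
                spec.n_patients, {k: round(v, 5) for k, v in hazards.items()},
                100 * spec.censoring_rate)
    return cohort, true_groups
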