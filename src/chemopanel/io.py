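"""File readers/writers, run configuration, and the end-to-end pipeline.

All on-disk formats are plain text: TSV for matrices and per-patient tables,
JSON for models and reports, YAML for run configuration. Every artifact
embeds the run seed and a hash of the configuration, so a pipeline run is a
deterministic, auditable function of (inputs, config).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .discovery import (
    ClassifierConfig,
    DrugResponseTable,
    GAConfig,
    TrainedPanelModel,
    assign_response_groups,
    ga_select,
    kruskal_wallis_filter,
    permutation_test,
    search_space_size,
    train_model,
)
from .preprocess import (
    ExpressionMatrix,
    ProbeAnnotation,
    collapse_probes,
    quantile_normalize,
    zscore_genes,
)
from .validation import (
    SurvivalCohort,
    classify_cohort,
    compare_survival,
    cox_fit,
    filter_cohort,
)

logger = logging.getLogger("chemopanel.io")

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotation",
    "read_drug_response",
    "read_clinical",
    "read_cohort",
    "write_model",
    "read_model",
    "RunConfig",
    "run_pipeline",
]


def read_expression(path) -> ExpressionMatrix:
    """Read a genes × samples TSV (first column ids, header = sample ids).

    Lines beginning with ``!`` (series-matrix style preamble) are skipped.
    Duplicate ids, non-numeric cells and ragged rows raise errors that name
    the offending line.
    """
    path = Path(path)
    header = None
    ids: list = []
    rows: list = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                if not header:
                    raise ValueError(f"{path}:{lineno}: header has no sample columns")
                continue
            if len(fields) != len(header) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header) + 1} fields, got {len(fields)}"
                )
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError:
                bad = next(x for x in fields[1:] if not _is_number(x))
                raise ValueError(f"{path}:{lineno}: non-numeric cell {bad!r}") from None
            ids.append(fields[0])
    if header is None:
        raise ValueError(f"{path}: no header line found")
    dup = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate gene/probe id(s): {dup[:5]}")
    return ExpressionMatrix(pd.DataFrame(rows, index=ids, columns=header))


def _is_number(x: str) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False


def write_expression(path, matrix: ExpressionMatrix) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="id", float_format="%.10g")


def read_annotation(path) -> ProbeAnnotation:
    """Two-column TSV probe_id → gene_symbol; repeated probes become non-unique."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="!")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation needs two columns (probe_id, gene_symbol)")
    return ProbeAnnotation.from_pairs(df.iloc[:, :2].itertuples(index=False, name=None))


_ACTIVITY_RE = re.compile(r"activity[_ ]?area", re.IGNORECASE)


def read_drug_response(path) -> DrugResponseTable:
    """Per-sample table with an activity-area column (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", comment="!")
    act_cols = [c for c in df.columns if _ACTIVITY_RE.search(str(c))]
    if not act_cols:
        raise ValueError(f"{path}: no activity-area column found in {list(df.columns)}")
    series = pd.Series(df[act_cols[0]].to_numpy(dtype=float),
                       index=df.iloc[:, 0].astype(str), name="activity_area")
    return DrugResponseTable(series)


def read_clinical(path) -> pd.DataFrame:
    """Per-patient clinical TSV with declared columns (id, time, event, ...)."""
    df = pd.read_csv(path, sep="\t", comment="!")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return df


def read_cohort(expression_path, clinical_path, endpoint: str = "OS") -> SurvivalCohort:
    expr = read_expression(expression_path)
    clin = read_clinical(clinical_path)
    return SurvivalCohort(expression=expr.data, clinical=clin, endpoint=endpoint)


def write_model(path, model: TrainedPanelModel, meta: dict | None = None) -> None:
    payload = model.to_dict()
    if meta:
        payload["run"] = meta
    Path(path).write_text(json.dumps(payload, indent=2))


def read_model(path) -> TrainedPanelModel:
    return TrainedPanelModel.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class RunConfig:
    """Configuration for the full discovery (+ optional validation) pipeline."""

    expression_path: str
    response_path: str
    output_dir: str
    annotation_path: str | None = None
    clinical_path: str | None = None
    cohort_expression_path: str | None = None
    quantile_normalization: bool = True
    drop_constant_genes: bool = True
    alpha: float = 0.01
    panel_size: int = 10
    n_permutations: int = 200
    permutation_pool: str = "significant"  # or "all"
    ga: GAConfig = field(default_factory=GAConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    min_survival_days: int = 30
    require_chemo: bool = True
    endpoint: str = "OS"
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        ga = GAConfig(**raw.pop("ga", {}))
        clf = ClassifierConfig(**raw.pop("classifier", {}))
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(ga=ga, classifier=clf, **raw)
        cfg.validate_paths()
        return cfg

    def validate_paths(self) -> None:
        required = {"expression_path": self.expression_path,
                    "response_path": self.response_path}
        optional = {"annotation_path": self.annotation_path,
                    "clinical_path": self.clinical_path,
                    "cohort_expression_path": self.cohort_expression_path}
        for name, p in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if p is None:
                raise ValueError(f"config is missing required path {name}")
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run preprocess → grouping → KW filter → GA → train → permutation,
    then (if a cohort is configured) classification and survival analysis.

    Writes panel JSON, permutation JSON, fitness-history CSV and, for the
    validation stage, per-patient labels CSV and a survival report JSON into
    ``config.output_dir``. Returns the artifact bundle as a dict.
    """
    config.validate_paths()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.rng_seed, "config_hash": config.config_hash()}
    bundle: dict = {"run": meta}

    current = {"stage": "init"}

    def stage(name):
        current["stage"] = name
        logger.info("stage %s: start", name)

    try:
        stage("preprocess")
        matrix = read_expression(config.expression_path)
        responses = read_drug_response(config.response_path)
        if config.quantile_normalization:
            matrix = quantile_normalize(matrix)
        if config.annotation_path:
            annot = read_annotation(config.annotation_path)
            matrix = collapse_probes(matrix, annot)
        matrix = zscore_genes(matrix, drop_constant=config.drop_constant_genes)

        stage("grouping")
        common = [s for s in responses.sample_ids if s in matrix.data.columns]
        if len(common) < len(responses.sample_ids):
            logger.warning("dropping %d response samples lacking expression",
                           len(responses.sample_ids) - len(common))
            responses = DrugResponseTable(responses.activity.loc[common])
        groups = assign_response_groups(responses)

        stage("kw_filter")
        pool, pvalues = kruskal_wallis_filter(matrix, groups, alpha=config.alpha)
        if len(pool) < config.panel_size:
            raise RuntimeError(
                f"only {len(pool)} genes pass the filter; need >= {config.panel_size}"
            )
        logger.info("search space: C(%d, %d) = %.3g combinations",
                    len(pool), config.panel_size,
                    float(search_space_size(len(pool), config.panel_size)))

        stage("ga_select")
        ga_cfg = dataclasses.replace(config.ga, rng_seed=config.rng_seed)
        panel, history = ga_select(pool, matrix, groups, ga_cfg,
                                   panel_size=config.panel_size,
                                   classifier_config=config.classifier)

        stage("train")
        model = train_model(panel, matrix, groups, config.classifier)
        write_model(out_dir / "panel_model.json", model, meta)
        pd.DataFrame({"generation": np.arange(1, len(history) + 1),
                      "best_fitness": history}).to_csv(
            out_dir / "fitness_history.csv", index=False)
        pvalues.to_csv(out_dir / "kw_pvalues.csv", header=True)
        bundle.update(model=model, fitness_history=history, kw_pvalues=pvalues,
                      significant_genes=pool)

        stage("permutation")
        perm_pool = pool if config.permutation_pool == "significant" else matrix.gene_ids
        perm = permutation_test(
            perm_pool, matrix, groups, n_trials=config.n_permutations,
            panel_size=config.panel_size, threshold_accuracy=model.loocv_accuracy,
            rng_seed=config.rng_seed + 1, classifier_config=config.classifier,
        )
        (out_dir / "permutation.json").write_text(json.dumps({
            **meta, "n_trials": perm.n_trials, "n_success": perm.n_success,
            "threshold_accuracy": perm.threshold_accuracy,
            "empirical_p": perm.empirical_p,
        }, indent=2))
        bundle["permutation"] = perm

        if config.clinical_path and config.cohort_expression_path:
            stage("validation")
            cohort = read_cohort(config.cohort_expression_path, config.clinical_path,
                                 endpoint=config.endpoint)
            cohort = filter_cohort(cohort, config.min_survival_days, config.require_chemo)
            labels = classify_cohort(model, cohort)
            labels.to_frame().assign(seed=config.rng_seed).to_csv(out_dir / "labels.csv")
            comparison = compare_survival(cohort, labels)
            cox_uni = cox_fit(cohort, ["panel_model"], "univariate", labels=labels)
            report = {
                **meta,
                "n_patients": cohort.n_patients,
                "group_counts": labels.value_counts().to_dict(),
                "logrank_statistic": comparison.statistic,
                "logrank_p": comparison.p_value,
                "hazard_ratio_high_vs_low": comparison.hazard_ratio,
                "hazard_ratio_ci": list(comparison.hr_ci),
                "cox_univariate": json.loads(cox_uni.table.to_json(orient="index")),
            }
            (out_dir / "survival_report.json").write_text(json.dumps(report, indent=2))
            bundle.update(labels=labels, survival=comparison, cox=cox_uni)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {current['stage']}: {exc}") from exc
    return bundle
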