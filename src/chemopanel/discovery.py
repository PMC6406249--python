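"""Panel discovery: tertile response groups, Kruskal-Wallis filter, GA wrapper
selection with leave-one-out SVM fitness, and the permutation empirical null.

The discovery design is a wrapper feature selection: candidate K-gene panels
are scored by the leave-one-out cross-validated accuracy of a three-class
support-vector classifier separating low/medium/high drug-response cell
lines, and a genetic algorithm searches the space of K-subsets of the
filter-passing gene pool. Statistical significance of the winning panel's
accuracy is assessed against random K-subsets drawn from the same pool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .preprocess import ExpressionMatrix

logger = logging.getLogger("chemopanel.discovery")

__all__ = [
    "GROUP_LABELS",
    "DrugResponseTable",
    "ResponseGroups",
    "ClassifierConfig",
    "GAConfig",
    "GenePanel",
    "TrainedPanelModel",
    "PermutationResult",
    "assign_response_groups",
    "kruskal_wallis_filter",
    "loocv_accuracy",
    "ga_select",
    "train_model",
    "permutation_test",
    "search_space_size",
]

#: Ordinal response labels, ascending in drug sensitivity (activity area).
GROUP_LABELS = ("low", "medium", "high")


@dataclass(frozen=True)
class DrugResponseTable:
    """Per-sample drug-efficacy summary (activity area; larger = more sensitive)."""

    activity: pd.Series  # sample_id -> activity area

    def __post_init__(self) -> None:
        s = self.activity
        if s.index.has_duplicates:
            raise ValueError("duplicate sample ids in drug response table")
        vals = s.to_numpy(dtype=float)
        if vals.size and not np.isfinite(vals).all():
            raise ValueError("non-finite activity area values")
        object.__setattr__(self, "activity", s.astype(float))

    @property
    def sample_ids(self) -> list:
        return list(self.activity.index)


@dataclass(frozen=True)
class ResponseGroups:
    """Ordinal low/medium/high response label per sample."""

    labels: pd.Series  # sample_id -> label

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list:
        return list(self.labels.index)

    def sizes(self) -> dict:
        counts = self.labels.value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUP_LABELS}

    def members(self, label: str) -> list:
        return list(self.labels.index[self.labels == label])


@dataclass(frozen=True)
class ClassifierConfig:
    """Three-class SVM settings. Linear kernel, C=1 is the small-n default."""

    kernel: str = "linear"
    C: float = 1.0

    def build(self) -> SVC:
        return SVC(kernel=self.kernel, C=self.C)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm search settings.

    Fitness-proportional (roulette) parent selection, single-point crossover
    on the gene list with duplicate repair, per-position mutation, elitism,
    and a global best-so-far memory. Ten generations suffice for the search
    to stabilize at the discovery scale (25 samples, a few hundred genes).
    """

    population_size: int = 100
    generations: int = 10
    crossover_rate: float = 0.9
    mutation_rate: float = 0.05
    elitism_count: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size <= 0 or self.generations <= 0:
            raise ValueError("population_size and generations must be positive")
        for name in ("crossover_rate", "mutation_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")


@dataclass(frozen=True)
class GenePanel:
    """Ordered set of exactly K unique genes plus per-gene training mean/sd."""

    genes: tuple
    means: tuple
    sds: tuple

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel genes must be unique")
        if not (len(self.genes) == len(self.means) == len(self.sds)):
            raise ValueError("genes, means and sds must align")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_matrix(cls, genes, matrix: ExpressionMatrix) -> "GenePanel":
        sub = matrix.subset_genes(genes).values
        return cls(
            genes=tuple(genes),
            means=tuple(float(m) for m in sub.mean(axis=1)),
            sds=tuple(float(s) for s in sub.std(axis=1, ddof=1)),
        )


def assign_response_groups(responses: DrugResponseTable, n_groups: int = 3) -> ResponseGroups:
    """Split samples into near-equal ordinal groups by ascending activity area.

    Group sizes are floor(n / n_groups) with the remainder distributed one
    sample each starting from the lowest group, so 25 samples give 9/8/8
    low/medium/high. Ties in activity area break by stable input order.
    """
    n = len(responses.activity)
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} samples, got {n}")
    if n_groups == 3:
        names = list(GROUP_LABELS)
    else:
        names = [f"group{i + 1}" for i in range(n_groups)]
    order = responses.activity.to_numpy().argsort(kind="mergesort")
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if i < rem else 0) for i in range(n_groups)]
    labels = np.empty(n, dtype=object)
    start = 0
    for name, size in zip(names, sizes):
        labels[order[start:start + size]] = name
        start += size
    series = pd.Series(labels, index=responses.activity.index, name="response_group")
    logger.info("assign_response_groups: n=%d sizes=%s", n, sizes)
    return ResponseGroups(labels=series)


def kruskal_wallis_filter(
    matrix: ExpressionMatrix,
    groups: ResponseGroups,
    alpha: float = 0.01,
):
    """Keep genes whose Kruskal-Wallis p-value across the response groups is < alpha.

    Uses the chi-square approximation (df = n_groups − 1) with tie correction.
    A gene constant across all samples has H = 0 and p = 1.

    Returns
    -------
    (selected, pvalues) : (list, pandas.Series)
        Gene ids passing the filter, and the per-gene p-value for reporting.
    """
    group_samples = {g: groups.members(g) for g in GROUP_LABELS}
    for g, members in group_samples.items():
        if not members:
            raise ValueError(f"group {g!r} has zero samples")
    missing = [s for s in groups.sample_ids if s not in matrix.data.columns]
    if missing:
        raise KeyError(f"samples in groups absent from matrix: {missing[:10]}")

    cols = {g: [matrix.data.columns.get_loc(s) for s in members]
            for g, members in group_samples.items()}
    values = matrix.values
    pvals = np.empty(values.shape[0])
    for i in range(values.shape[0]):
        row = values[i]
        if (row == row[0]).all():
            # constant gene: H = 0, no evidence of group differences
            pvals[i] = 1.0
            continue
        parts = [row[idx] for idx in cols.values()]
        _, p = stats.kruskal(*parts)
        pvals[i] = p
    pvalues = pd.Series(pvals, index=matrix.data.index, name="kw_pvalue")
    selected = list(pvalues.index[pvalues < alpha])
    logger.info("kruskal_wallis_filter: %d/%d genes pass at alpha=%g",
                len(selected), len(pvalues), alpha)
    return selected, pvalues


def _design(genes, matrix: ExpressionMatrix, groups: ResponseGroups):
    """Feature matrix (samples × genes) and label vector aligned to groups."""
    samples = groups.sample_ids
    X = matrix.subset_genes(genes).data[samples].to_numpy().T
    y = groups.labels.loc[samples].to_numpy()
    return X, y


def loocv_accuracy(
    genes,
    matrix: ExpressionMatrix,
    groups: ResponseGroups,
    classifier_config: ClassifierConfig | None = None,
) -> float:
    """Leave-one-out cross-validated accuracy of the three-class SVM on a gene subset.

    Every sample is predicted by a classifier trained on all other samples
    restricted to ``genes``; the fraction of correct predictions is returned.
    Every group must have at least two samples so each fold keeps all classes.
    """
    cfg = classifier_config or ClassifierConfig()
    X, y = _design(genes, matrix, groups)
    labels, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        small = labels[counts.argmin()]
        raise ValueError(
            f"group {small!r} has {counts.min()} sample(s); a leave-one-out fold "
            "would lose the class entirely"
        )
    n = len(y)
    correct = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = cfg.build()
        clf.fit(X[mask], y[mask])
        correct += int(clf.predict(X[i:i + 1])[0] == y[i])
        mask[i] = True
    return correct / n


class _FitnessCache:
    """Memoized LOOCV fitness keyed by the (unordered) gene subset."""

    def __init__(self, matrix, groups, classifier_config):
        self.matrix = matrix
        self.groups = groups
        self.config = classifier_config
        self._cache: dict = {}

    def __call__(self, genes) -> float:
        key = frozenset(genes)
        if key not in self._cache:
            self._cache[key] = loocv_accuracy(list(genes), self.matrix, self.groups, self.config)
        return self._cache[key]


def _repair_duplicates(child: np.ndarray, pool: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace duplicate gene indices with uniform draws from the unused pool."""
    seen: set = set()
    dup_positions = []
    for pos, g in enumerate(child):
        if g in seen:
            dup_positions.append(pos)
        else:
            seen.add(g)
    if dup_positions:
        unused = np.array([g for g in pool if g not in seen])
        picks = rng.choice(len(unused), size=len(dup_positions), replace=False)
        for pos, k in zip(dup_positions, picks):
            child[pos] = unused[k]
    return child


def ga_select(
    pool,
    matrix: ExpressionMatrix,
    groups: ResponseGroups,
    config: GAConfig | None = None,
    panel_size: int = 10,
    classifier_config: ClassifierConfig | None = None,
):
    """Search K-gene panels by a genetic algorithm with LOOCV-SVM fitness.

    Individuals are K-subsets of ``pool``. Parents are drawn with probability
    proportional to fitness; single-point crossover on the gene list is
    followed by repair of duplicate genes; each position mutates to a random
    unused pool gene with ``mutation_rate``. The best individual ever seen is
    kept in a global elitist memory and returned, so the best-so-far fitness
    history is non-decreasing. Fully reproducible from ``config.rng_seed``.

    Returns
    -------
    (panel, history) : (GenePanel, list of float)
        The best panel found and the best-so-far fitness after each generation.
    """
    cfg = config or GAConfig()
    pool = list(pool)
    if len(set(pool)) != len(pool):
        raise ValueError("gene pool contains duplicates")
    if len(pool) < panel_size:
        raise ValueError(f"pool has {len(pool)} genes; need at least panel_size={panel_size}")
    fitness = _FitnessCache(matrix, groups, classifier_config)
    pool_arr = np.arange(len(pool))
    rng = np.random.default_rng(cfg.rng_seed)

    if len(pool) == panel_size:
        f = fitness(pool)
        logger.info("ga_select: pool equals panel size; single combination, fitness=%.4f", f)
        return GenePanel.from_matrix(pool, matrix), [f]

    def genes_of(ind: np.ndarray):
        return [pool[k] for k in ind]

    population = [rng.choice(pool_arr, size=panel_size, replace=False)
                  for _ in range(cfg.population_size)]
    best_ind: np.ndarray | None = None
    best_fit = -1.0
    history: list = []

    for gen in range(cfg.generations):
        fits = np.array([fitness(genes_of(ind)) for ind in population])
        top = int(fits.argmax())
        if fits[top] > best_fit:
            best_fit = float(fits[top])
            best_ind = population[top].copy()
        history.append(best_fit)
        logger.info("ga_select: generation %d best=%.4f (overall %.4f)",
                    gen + 1, fits.max(), best_fit)
        if gen == cfg.generations - 1:
            break

        # fitness-proportional selection; degenerate all-zero fitness -> uniform
        total = fits.sum()
        probs = fits / total if total > 0 else np.full(len(fits), 1 / len(fits))
        elite_order = np.argsort(fits, kind="mergesort")[::-1][: cfg.elitism_count]
        next_pop = [population[k].copy() for k in elite_order]
        while len(next_pop) < cfg.population_size:
            pa, pb = rng.choice(len(population), size=2, p=probs)
            a, b = population[pa].copy(), population[pb].copy()
            if rng.random() < cfg.crossover_rate:
                point = int(rng.integers(1, panel_size))
                a = np.concatenate([a[:point], b[point:]])
            for pos in range(panel_size):
                if rng.random() < cfg.mutation_rate:
                    a[pos] = rng.choice(pool_arr)
            next_pop.append(_repair_duplicates(a, pool_arr, rng))
        population = next_pop

    assert best_ind is not None
    return GenePanel.from_matrix(genes_of(best_ind), matrix), history


@dataclass(frozen=True)
class TrainedPanelModel:
    """A gene panel with its fitted three-class decision rule.

    Stores the standardized training features and labels so the (deterministic)
    SVM fit can be reproduced exactly from a serialized model.
    """

    panel: GenePanel
    classifier_config: ClassifierConfig
    classifier: SVC = field(repr=False, compare=False)
    class_order: tuple = GROUP_LABELS
    loocv_accuracy: float = float("nan")
    training_features: np.ndarray = field(default=None, repr=False, compare=False)
    training_labels: np.ndarray = field(default=None, repr=False, compare=False)

    def standardize(self, features: pd.DataFrame) -> pd.DataFrame:
        """Apply the panel's training mean/sd to a samples × genes frame."""
        aligned = features[list(self.panel.genes)]
        return (aligned - np.asarray(self.panel.means)) / np.asarray(self.panel.sds)

    def predict(self, standardized: pd.DataFrame) -> pd.Series:
        """Predict low/medium/high for pre-standardized samples × genes features."""
        vals = standardized[list(self.panel.genes)].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("non-finite features passed to predict")
        return pd.Series(self.classifier.predict(vals), index=standardized.index,
                         name="predicted_group")

    def to_dict(self) -> dict:
        return {
            "genes": list(self.panel.genes),
            "means": list(self.panel.means),
            "sds": list(self.panel.sds),
            "classifier_config": {"kernel": self.classifier_config.kernel,
                                  "C": self.classifier_config.C},
            "class_order": list(self.class_order),
            "loocv_accuracy": self.loocv_accuracy,
            "training_features": np.asarray(self.training_features).tolist(),
            "training_labels": np.asarray(self.training_labels).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedPanelModel":
        panel = GenePanel(genes=tuple(d["genes"]), means=tuple(d["means"]), sds=tuple(d["sds"]))
        cfg = ClassifierConfig(**d["classifier_config"])
        X = np.asarray(d["training_features"], dtype=float)
        y = np.asarray(d["training_labels"], dtype=object)
        clf = cfg.build()
        clf.fit(X, y)
        return cls(panel=panel, classifier_config=cfg, classifier=clf,
                   class_order=tuple(d["class_order"]),
                   loocv_accuracy=float(d["loocv_accuracy"]),
                   training_features=X, training_labels=y)


def train_model(
    panel: GenePanel,
    matrix: ExpressionMatrix,
    groups: ResponseGroups,
    classifier_config: ClassifierConfig | None = None,
) -> TrainedPanelModel:
    """Fit the three-class SVM on the panel's standardized training features."""
    cfg = classifier_config or ClassifierConfig()
    if any(s == 0 for s in panel.sds):
        bad = [g for g, s in zip(panel.genes, panel.sds) if s == 0]
        raise ValueError(f"constant panel genes cannot be standardized: {bad}")
    X_raw, y = _design(list(panel.genes), matrix, groups)
    X = (X_raw - np.asarray(panel.means)) / np.asarray(panel.sds)
    clf = cfg.build()
    clf.fit(X, y)
    acc = loocv_accuracy(list(panel.genes), matrix, groups, cfg)
    resub = (clf.predict(X) == y).mean()
    logger.info("train_model: resubstitution accuracy %.4f, LOOCV accuracy %.4f", resub, acc)
    return TrainedPanelModel(
        panel=panel, classifier_config=cfg, classifier=clf,
        class_order=GROUP_LABELS, loocv_accuracy=acc,
        training_features=X, training_labels=y,
    )


@dataclass(frozen=True)
class PermutationResult:
    """Empirical null for panel accuracy from random K-subsets of the pool."""

    n_trials: int
    n_success: int
    threshold_accuracy: float = 1.0
    accuracies: tuple = ()

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 <= self.n_success <= self.n_trials:
            raise ValueError("n_success must be in [0, n_trials]")
        if self.accuracies and len(self.accuracies) != self.n_trials:
            raise ValueError("per-trial accuracies must have length n_trials")
        if self.accuracies:
            expected = sum(a >= self.threshold_accuracy for a in self.accuracies)
            if expected != self.n_success:
                raise ValueError("n_success inconsistent with per-trial accuracies")

    @property
    def empirical_p(self) -> float:
        return self.n_success / self.n_trials


def permutation_test(
    pool,
    matrix: ExpressionMatrix,
    groups: ResponseGroups,
    n_trials: int,
    panel_size: int = 10,
    threshold_accuracy: float = 1.0,
    rng_seed: int = 0,
    classifier_config: ClassifierConfig | None = None,
) -> PermutationResult:
    """Estimate how often a random K-gene panel matches the observed accuracy.

    Each trial draws ``panel_size`` genes uniformly without replacement from
    ``pool`` and scores them with the same LOOCV protocol used as the GA
    fitness; the empirical p-value is the fraction of trials whose accuracy
    reaches ``threshold_accuracy``. Trials are independent, so the same
    combination may recur across trials.
    """
    pool = list(pool)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if len(pool) < panel_size:
        raise ValueError(f"pool has {len(pool)} genes; need at least panel_size={panel_size}")
    if not 0.0 <= threshold_accuracy <= 1.0:
        raise ValueError("threshold_accuracy must be in [0, 1]")
    fitness = _FitnessCache(matrix, groups, classifier_config)
    rng = np.random.default_rng(rng_seed)
    accs = []
    for _ in range(n_trials):
        idx = rng.choice(len(pool), size=panel_size, replace=False)
        accs.append(fitness([pool[k] for k in idx]))
    n_success = sum(a >= threshold_accuracy for a in accs)
    logger.info("permutation_test: %d/%d trials reached accuracy >= %g (p=%.4g)",
                n_success, n_trials, threshold_accuracy, n_success / n_trials)
    return PermutationResult(n_trials=n_trials, n_success=n_success,
                             threshold_accuracy=threshold_accuracy,
                             accuracies=tuple(accs))


def search_space_size(pool_size: int, panel_size: int) -> int:
    """Exact number of panel_size-subsets of a pool (binomial coefficient)."""
    return math.comb(pool_size, panel_size)
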