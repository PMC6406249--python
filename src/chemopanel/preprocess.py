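"""Probe-level preprocessing: quantile normalization, probe→gene collapse, z-scoring.

Turns a raw probes × samples intensity matrix into a gene-level matrix whose
rows are standard-normal scaled, the form consumed by the downstream filter,
panel search and cross-cohort transfer steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("chemopanel.preprocess")

__all__ = [
    "ExpressionMatrix",
    "ProbeAnnotation",
    "quantile_normalize",
    "collapse_probes",
    "zscore_genes",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes (or probes) × samples real-valued expression matrix.

    Thin validated wrapper around a :class:`pandas.DataFrame`; the index holds
    gene/probe identifiers and the columns hold sample identifiers. Values are
    arbitrary positive intensity units before standardization and z-units after.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise TypeError("ExpressionMatrix.data must be a pandas DataFrame")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene/probe ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        values = df.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            raise ValueError("expression matrix contains missing or non-finite entries")
        object.__setattr__(self, "data", df.astype(float))

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[list(genes)])


@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe → gene-symbol map; probes hitting zero or several symbols are flagged.

    ``mapping`` holds only uniquely-mapped probes. ``non_unique`` holds probes
    annotated to multiple gene symbols (or repeated in the source table);
    those are excluded from gene-level analyses.
    """

    mapping: dict = field(default_factory=dict)
    non_unique: frozenset = frozenset()

    def __post_init__(self) -> None:
        overlap = set(self.mapping) & set(self.non_unique)
        if overlap:
            raise ValueError(f"probes both uniquely and non-uniquely mapped: {sorted(overlap)[:5]}")

    @classmethod
    def from_pairs(cls, pairs) -> "ProbeAnnotation":
        """Build from (probe_id, gene_symbol) pairs; repeated probe ids → non-unique."""
        seen: dict = {}
        non_unique = set()
        for probe, gene in pairs:
            probe, gene = str(probe), str(gene)
            if probe in non_unique:
                continue
            if probe in seen and seen[probe] != gene:
                del seen[probe]
                non_unique.add(probe)
            else:
                seen[probe] = gene
        return cls(mapping=seen, non_unique=frozenset(non_unique))

    def gene_for(self, probe: str) -> str:
        if probe in self.non_unique:
            raise KeyError(f"probe {probe!r} maps to multiple gene symbols")
        try:
            return self.mapping[probe]
        except KeyError:
            raise KeyError(f"unknown probe {probe!r}") from None

    def is_unique(self, probe: str) -> bool:
        if probe in self.mapping:
            return True
        if probe in self.non_unique:
            return False
        raise KeyError(f"unknown probe {probe!r}")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) to share the same value distribution.

    Each column's sorted values are replaced by the rank-wise means taken
    across all columns; within a column, tied values receive the mean of the
    rank means over their tied span. The operation is idempotent.
    """
    values = matrix.values
    n_genes, n_samples = values.shape
    if n_samples < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    rank_means = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        # group runs of equal values (contiguous after sorting) and average
        # the rank means over each run
        _, inverse = np.unique(col[order], return_inverse=True)
        group_means = np.bincount(inverse, weights=rank_means) / np.bincount(inverse)
        out[order, j] = group_means[inverse]
    logger.info("quantile_normalize: %d genes x %d samples", n_genes, n_samples)
    return ExpressionMatrix(pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns))


def _coefficient_of_variation(row: np.ndarray, probe: str) -> float:
    mean = row.mean()
    if mean <= 0:
        raise ValueError(f"probe {probe!r} has mean {mean:g} <= 0; CV undefined")
    return float(row.std(ddof=1) / mean)


def collapse_probes(matrix: ExpressionMatrix, annot: ProbeAnnotation) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per uniquely-mapped gene symbol.

    Probes without a unique gene symbol are dropped. When several probes
    annotate the same gene, the probe with the largest coefficient of
    variation (sample sd / mean across samples) is retained.
    """
    values = matrix.values
    best: dict = {}  # gene -> (cv, probe, row_idx)
    gene_order: list = []
    n_dropped = 0
    for i, probe in enumerate(matrix.gene_ids):
        if not annot.is_unique(probe):
            n_dropped += 1
            continue
        gene = annot.mapping[probe]
        cv = _coefficient_of_variation(values[i], probe)
        if gene not in best:
            gene_order.append(gene)
            best[gene] = (cv, i)
        elif cv > best[gene][0]:
            best[gene] = (cv, i)
    if not best:
        raise ValueError("no uniquely-mapped probes remain after collapsing")
    rows = [best[g][1] for g in gene_order]
    logger.info(
        "collapse_probes: %d probes -> %d genes (%d non-uniquely mapped dropped)",
        len(matrix.gene_ids), len(gene_order), n_dropped,
    )
    return ExpressionMatrix(
        pd.DataFrame(values[rows], index=gene_order, columns=matrix.data.columns)
    )


def zscore_genes(matrix: ExpressionMatrix, drop_constant: bool = False) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, sample sd 1 (denominator n−1).

    Constant rows are an error naming the gene, unless ``drop_constant`` is
    set, in which case they are removed and logged.
    """
    values = matrix.values
    sds = values.std(axis=1, ddof=1)
    constant = sds == 0
    if constant.any():
        names = [g for g, c in zip(matrix.gene_ids, constant) if c]
        if not drop_constant:
            raise ValueError(
                f"constant gene rows (zero sd) cannot be z-scored: {names[:10]}"
            )
        logger.warning("zscore_genes: dropping %d constant genes: %s", len(names), names[:10])
        keep = ~constant
        values = values[keep]
        sds = sds[keep]
        index = matrix.data.index[keep]
    else:
        index = matrix.data.index
    if values.shape[0] == 0:
        raise ValueError("no genes remain after dropping constant rows")
    means = values.mean(axis=1)
    z = (values - means[:, None]) / sds[:, None]
    return ExpressionMatrix(pd.DataFrame(z, index=index, columns=matrix.data.columns))
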