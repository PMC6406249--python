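"""Shared fixtures: the planted-signal discovery fixture and a trained model.

Everything is generated programmatically with fixed seeds; the expensive GA
run over the 25 × 50 separable fixture is session-scoped so the discovery
property tests and the acceptance suite share a single search.
"""

from types import SimpleNamespace

import pytest

from chemopanel import (
    CellLineSimSpec,
    GAConfig,
    GenePanel,
    ga_select,
    gen_cell_line_dataset,
    train_model,
    zscore_genes,
)

#: Study-scale separable fixture: 25 lines, 10 planted genes among 40 noise,
#: class-mean shift 3 sd, 9/8/8 tertile groups.
SEPARABLE_SPEC = CellLineSimSpec(
    n_cell_lines=25, n_genes=50, n_signal_genes=10,
    effect_size=3.0, noise_sd=1.0, rng_seed=0,
)


@pytest.fixture(scope="session")
def separable():
    matrix, responses, signal_genes, groups = gen_cell_line_dataset(SEPARABLE_SPEC)
    return SimpleNamespace(
        matrix=matrix,
        z=zscore_genes(matrix),
        responses=responses,
        signal_genes=signal_genes,
        groups=groups,
    )


@pytest.fixture(scope="session")
def ga_result(separable):
    """One full-size GA search (population 100, 10 generations, seed 0)."""
    panel, history = ga_select(
        separable.z.gene_ids, separable.z, separable.groups,
        GAConfig(population_size=100, generations=10, rng_seed=0),
        panel_size=10,
    )
    return SimpleNamespace(panel=panel, history=history)


@pytest.fixture(scope="session")
def trained_model(separable):
    """Model trained on the planted panel itself (known-good features)."""
    panel = GenePanel.from_matrix(separable.signal_genes, separable.z)
    return train_model(panel, separable.z, separable.groups)
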