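import numpy as np
import pandas as pd
import pytest

from dmhseq import CountMatrix, GeneratorConfig, simulate_counts

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def make_count_matrix(counts, gene_ids=None, conditions=None) -> CountMatrix:
    """Small CountMatrix from a dense array, with default labels."""
    counts = np.asarray(counts)
    n_genes, n_cols = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    cols = [f"c{j}" for j in range(n_cols)]
    conditions = conditions or ["A"] * n_cols
    labels = pd.DataFrame(
        {"sample": [f"s{j}" for j in range(n_cols)], "condition": conditions},
        index=cols,
    )
    return CountMatrix(counts, gene_ids, cols, labels)


@pytest.fixture(scope="session")
def small_sim():
    """One small default-structure simulation shared across read-only tests."""
    cfg = GeneratorConfig(n_genes=600, n_cells_per_condition=250, seed=11)
    return simulate_counts(cfg), cfg
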