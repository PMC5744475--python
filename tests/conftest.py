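import numpy as np
import pandas as pd
import pytest

import dryseed as ds


@pytest.fixture(scope="session")
def small_config() -> ds.SimulationConfig:
    """1000-gene design, same group structure as the full study."""
    return ds.SimulationConfig(n_genes=1000, n_control_probes=10, rng_seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    annotation, truth = ds.generate_annotation(small_config)
    matrix = ds.generate_expression(small_config, truth)
    return annotation, truth, matrix


@pytest.fixture(scope="session")
def small_genesets(small_config, small_dataset):
    _, truth, _ = small_dataset
    return ds.generate_genesets(small_config, truth)


def two_group_matrix(values_a: np.ndarray, values_b: np.ndarray, gene_ids=None) -> ds.ExpressionMatrix:
    """Assemble an ExpressionMatrix from per-group value arrays (genes x reps)."""
    values_a, values_b = np.atleast_2d(values_a), np.atleast_2d(values_b)
    n = values_a.shape[0]
    gene_ids = gene_ids or [f"g{i}" for i in range(n)]
    cols_a = [f"A_r{j}" for j in range(values_a.shape[1])]
    cols_b = [f"B_r{j}" for j in range(values_b.shape[1])]
    vals = pd.DataFrame(
        np.hstack([values_a, values_b]), index=gene_ids, columns=cols_a + cols_b
    )
    meta = pd.DataFrame(
        {"group": ["A"] * len(cols_a) + ["B"] * len(cols_b)}, index=cols_a + cols_b
    )
    return ds.ExpressionMatrix(vals, meta)
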