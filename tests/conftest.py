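import numpy as np
import pandas as pd
import pytest

import exprmap as em


@pytest.fixture
def tiny_matrix():
    """3 genes × 5 conditions in two experiments, one missing value."""
    df = pd.DataFrame(
        [[11.0, 4.0, 6.0, 1.0, 2.0],
         [1.0, 2.0, 3.0, 4.0, 5.0],
         [0.5, np.nan, -0.5, 2.0, -2.0]],
        index=["g1", "g2", "g3"],
        columns=["a1", "a2", "a3", "b1", "b2"],
    )
    exp = {"a1": "expA", "a2": "expA", "a3": "expA", "b1": "expB", "b2": "expB"}
    return em.ExpressionMatrix(df, exp)


@pytest.fixture(scope="session")
def synthetic_data():
    """1000 genes, 8 planted clusters, 20 conditions across 4 experiments."""
    spec = em.SyntheticSpec(n_genes=1000, n_clusters=8, seed=42)
    matrix, truth = em.generate_matrix(spec)
    return em.median_shift(matrix), truth


@pytest.fixture(scope="session")
def trained_map(synthetic_data):
    """A 15×10 map trained on the synthetic compendium."""
    matrix, _ = synthetic_data
    return em.train(matrix, em.SomConfig(width=15, height=10, seed=42))


@pytest.fixture(scope="session")
def coarse_map(synthetic_data):
    """A 6×5 map on the same data: few large clusters (~30+ genes each),
    useful where per-node gene counts must be large."""
    matrix, _ = synthetic_data
    return em.train(matrix, em.SomConfig(width=6, height=5, radius0=3.0, seed=42))
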