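"""Shared fixtures: small synthetic expression matrices and cluster labels."""

import numpy as np
import pytest
import scipy.sparse as sp

from stabmark import AnalysisConfig, ClusterAnnotation, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng):
    """20 genes x 30 cells of sparse Poisson counts, no empty cells."""
    counts = rng.poisson(1.2, size=(20, 30)).astype(float)
    counts[:, counts.sum(axis=0) == 0] += 1  # guard: no zero-count cells
    return ExpressionMatrix(
        sp.csr_matrix(counts),
        [f"g{i}" for i in range(20)],
        [f"c{j}" for j in range(30)],
        scale="counts",
    )


@pytest.fixture
def two_cluster_ann():
    labels = {f"c{j}": ("A" if j < 15 else "B") for j in range(30)}
    return ClusterAnnotation(labels=labels)


@pytest.fixture
def fast_config():
    """Config small enough for unit tests of the stage functions."""
    return AnalysisConfig(
        n_lasso_iter=20, theta=16, n_null_genes=15, n_null_rounds=5,
        n_boot=20, K=16, n_lambda=3, min_target_cells=5, seed=7,
    )


def dense_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson correlation oracle on dense vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return float("nan")
    return float((xc * yc).sum() / denom)
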