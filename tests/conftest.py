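import numpy as np
import pytest

from scmarkers import (
    CellLabels,
    ExpressionMatrix,
    SyntheticConfig,
    filter_genes,
    normalize_counts,
    simulate,
)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 cells x 4 genes with one all-zero gene (g2)."""
    values = np.array(
        [
            [1.0, 2.0, 0.0, 3.0],
            [0.0, 1.0, 0.0, 4.0],
            [2.0, 0.0, 0.0, 5.0],
        ]
    )
    return ExpressionMatrix(values, ["c0", "c1", "c2"], ["g0", "g1", "g2", "g3"])


@pytest.fixture
def tiny_labels() -> CellLabels:
    return CellLabels(["c0", "c1", "c2"], ["A", "B", "A"])


@pytest.fixture(scope="session")
def small_dataset():
    """Quick simulated dataset: 300 cells, 200 genes, 3 types, 8 markers/type."""
    cfg = SyntheticConfig(
        n_cells=300, n_genes=200, n_types=3, markers_per_type=8,
        log2_fold_change=2.0, dispersion=0.5, seed=11,
    )
    X, y, markers = simulate(cfg)
    return X, y, markers, cfg


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    X, y, markers, cfg = small_dataset
    return normalize_counts(filter_genes(X)), y, markers


@pytest.fixture(scope="session")
def standard_fixture():
    """The reference simulation: 1,200 cells, 2,000 genes, 6 types,
    10 markers/type, log2 fold change 2, seed 7."""
    cfg = SyntheticConfig(
        n_cells=1200, n_genes=2000, n_types=6, markers_per_type=10,
        log2_fold_change=2.0, dispersion=0.5, seed=7,
    )
    X, y, markers = simulate(cfg)
    return X, y, markers, cfg
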