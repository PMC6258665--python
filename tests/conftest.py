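import numpy as np
import pytest

from dropatlas.io import CountMatrix
from dropatlas import simulate


@pytest.fixture
def toy_matrix() -> CountMatrix:
    """2 genes x 3 cells with hand-checkable counts."""
    return CountMatrix(
        gene_ids=["gA", "gB"],
        barcodes=["c1", "c2", "c3"],
        counts=np.array([[5, 0, 2], [1, 3, 0]]),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A modest atlas-like simulation shared across read-only tests."""
    cfg = simulate.default_config(
        n_cells=2000, n_genes=300, ambient_n_barcodes=0, doublet_rate=0.0, seed=42
    )
    matrix, truth = simulate.simulate_counts(cfg)
    return cfg, matrix, truth
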