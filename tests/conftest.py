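import numpy as np
import pytest

from lagsc import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cm():
    """3 genes x 2 cells with one mitochondrial gene."""
    return CountMatrix(
        counts=np.array([[5, 0], [0, 0], [0, 2]]),
        gene_ids=["YAL001C", "YBR002W", "Q0045"],
        barcodes=["AAAC", "AAAG"],
        sample_label="toy",
    )


def random_count_matrix(rng, n_genes=20, n_cells=50, density=0.3, max_count=40):
    counts = rng.integers(1, max_count, size=(n_genes, n_cells))
    counts[rng.random((n_genes, n_cells)) > density] = 0
    return CountMatrix(
        counts=counts,
        gene_ids=[f"G{i:03d}" for i in range(n_genes)],
        barcodes=[f"BC{i:03d}" for i in range(n_cells)],
        sample_label="random",
        mito_flags=rng.random(n_genes) < 0.1,
    )
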