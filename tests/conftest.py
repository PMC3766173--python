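import numpy as np
import pytest

from osrr import ExpressionMatrix, center_genes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(rng, n_genes, n_samples, prefix="g", centered=False):
    m = ExpressionMatrix(
        values=rng.standard_normal((n_genes, n_samples)),
        gene_ids=[f"{prefix}{i:03d}" for i in range(n_genes)],
        sample_ids=[f"s{j:03d}" for j in range(n_samples)],
    )
    return center_genes(m) if centered else m


@pytest.fixture
def small_centered(rng):
    """8 genes x 6 samples, centered."""
    return make_matrix(rng, 8, 6, centered=True)
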