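import numpy as np
import pytest

from tdmnorm import ExpressionMatrix


@pytest.fixture
def tiny_matrix():
    """3 genes x 2 samples, log2 space."""
    return ExpressionMatrix(
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2"],
        values=np.array([[1.0, 2.0], [3.5, 4.25], [0.0, 7.125]]),
        space="log2",
    )


def random_matrix(rng, n_genes=30, n_samples=20, space="linear", scale=100.0):
    values = rng.gamma(shape=2.0, scale=scale, size=(n_genes, n_samples))
    if space == "log2":
        values = np.log2(values + 1.0)
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        values=values,
        space=space,
    )
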