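import numpy as np
import pytest

from netimpute.matrix import ExpressionMatrix

# Reduced-scale study conditions used by the slower integration tests:
# one-tenth the genes and DE genes of the full design, same cell layout,
# dropout intensity at the most severe level (~87% zeros).
REDUCED_SIM = dict(n_genes=2000, n_cells=150, n_types=3, de_genes_per_type=81,
                   dropout_lambda=0.04)


def make_expr(values, scale_tag="counts", gene_ids=None, cell_ids=None):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(m)]
    if cell_ids is None:
        cell_ids = [f"c{j}" for j in range(n)]
    return ExpressionMatrix(values, gene_ids, cell_ids, scale_tag)


@pytest.fixture
def small_counts():
    return make_expr([[1, 2, 0], [3, 6, 1], [0, 0, 5], [2, 1, 1]])


def random_adjacency(p, density, rng):
    """Random symmetric binary adjacency, zero diagonal."""
    A = (rng.random((p, p)) < density).astype(int)
    A = ((A + A.T) > 0).astype(np.int8)
    np.fill_diagonal(A, 0)
    return A
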