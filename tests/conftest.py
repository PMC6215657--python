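import numpy as np
import pandas as pd
import pytest

from regprob.data import ExpressionDataset


def make_dataset(tumor, normal, gene_ids=None):
    """Build an ExpressionDataset from (genes, n) and (genes, m) arrays."""
    tumor = np.atleast_2d(np.asarray(tumor, dtype=float))
    normal = np.atleast_2d(np.asarray(normal, dtype=float))
    G, n = tumor.shape
    m = normal.shape[1]
    genes = gene_ids or [f"g{i}" for i in range(G)]
    samples = [f"t{i}" for i in range(n)] + [f"c{j}" for j in range(m)]
    values = pd.DataFrame(np.hstack([tumor, normal]), index=genes, columns=samples)
    classes = pd.Series(["tumor"] * n + ["normal"] * m, index=samples)
    return ExpressionDataset(values, classes)


@pytest.fixture
def toy_dataset():
    """Two genes from the worked examples: T = [-0.5, 1] under aGRP."""
    return make_dataset([[3, 1], [5, 3]], [[2, 4], [1, 2]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_pair_count(tumor, normal):
    """#{(i, j): tumor_i >= normal_j} by explicit enumeration."""
    return sum(1 for a in tumor for b in normal if a >= b)
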