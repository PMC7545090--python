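import numpy as np
import pytest

from rwrnet.io_formats import ExpressionMatrix
from rwrnet.mi_estimation import MIMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def expr_tsv(tmp_path):
    """3-gene x 4-sample expression TSV (genes in rows)."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene_id\tS1\tS2\tS3\tS4\n"
        "G1\t1.0\t2.0\t3.0\t4.0\n"
        "G2\t2.5\t1.5\t0.5\t3.5\n"
        "G3\t0.1\t0.2\t0.4\t0.8\n"
    )
    return path


@pytest.fixture
def small_expr(rng):
    return ExpressionMatrix(
        gene_ids=[f"G{i + 1}" for i in range(4)],
        values=rng.normal(size=(4, 50)),
    )


def random_mi(n, seed=0, low=0.05, high=1.0):
    r = np.random.default_rng(seed)
    m = r.uniform(low, high, size=(n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return MIMatrix(gene_ids=[f"G{i + 1}" for i in range(n)], values=m)


@pytest.fixture
def mi5():
    return random_mi(5, seed=7)
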