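import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from netreg.expression import ExpressionMatrix

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def two_triangles() -> nx.Graph:
    """Two triangles {0,1,2} and {3,4,5} joined by the bridge edge 2-3."""
    return nx.Graph([(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)])


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """Four genes x 3+3 samples with one obvious up gene and one null gene."""
    rng = np.random.default_rng(7)
    genes = ["UP1", "NULL1", "DOWN1", "NULL2"]
    base = rng.normal(8.0, 0.2, size=(4, 6))
    base[0, 3:] += 3.0
    base[2, 3:] -= 3.0
    samples = ["c1", "c2", "c3", "t1", "t2", "t3"]
    groups = pd.Series(["control"] * 3 + ["case"] * 3, index=samples)
    return ExpressionMatrix(pd.DataFrame(base, index=genes, columns=samples), groups)


@pytest.fixture
def toy_deg_records() -> pd.DataFrame:
    """Five records spanning all pass/fail combinations of the thresholds."""
    return pd.DataFrame(
        {
            "log2fc": [1.2, -1.0, 0.9, 2.0, -3.0],
            "p": [0.01, 0.04, 0.001, 0.06, 0.01],
            "padj": [0.01, 0.05, 0.001, 0.04, 0.06],
        },
        index=pd.Index(["A", "B", "C", "D", "E"], name="gene"),
    )


def random_graph(rng: np.random.Generator, n_max: int = 12) -> nx.Graph:
    """Small random graph for brute-force oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.15, 0.7))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    return g
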