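import numpy as np
import pandas as pd
import pytest

from ppisig.network import PPINetwork
from ppisig.prep import ClinicalTable, ExpressionMatrix


@pytest.fixture
def triangle() -> PPINetwork:
    return PPINetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3() -> PPINetwork:
    return PPINetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def block_dissimilarity():
    """Two tight blocks (sizes 6 and 8), within <= 0.2, between 1.0."""
    rng = np.random.RandomState(7)
    sizes = [6, 8]
    n = sum(sizes)
    d = np.ones((n, n))
    start = 0
    for s in sizes:
        block = rng.uniform(0.05, 0.2, size=(s, s))
        block = (block + block.T) / 2
        d[start : start + s, start : start + s] = block
        start += s
    np.fill_diagonal(d, 0.0)
    labels = np.repeat([1, 2], sizes)
    return d, labels


def toy_clinical(times, events, covariate, name="x") -> ClinicalTable:
    n = len(times)
    df = pd.DataFrame(
        {
            "rfs_time": np.asarray(times, dtype=float),
            "rfs_event": np.asarray(events, dtype=int),
            "treatment": np.zeros(n, dtype=int),
            name: np.asarray(covariate, dtype=float),
        },
        index=[f"s{i}" for i in range(n)],
    )
    return ClinicalTable(df)


def small_expression(values, genes=None, samples=None) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))
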