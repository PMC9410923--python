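import numpy as np
import pytest

from stresscluster import (
    ScaleSpec,
    ScoreMatrix,
    similarity_matrix,
    table2_fixture,
    transitive_closure,
)


@pytest.fixture(scope="session")
def table2():
    return table2_fixture()


@pytest.fixture(scope="session")
def table2_closure(table2):
    return transitive_closure(similarity_matrix(table2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_scores(values, scale=None) -> ScoreMatrix:
    """1-D or 2-D raw values -> ScoreMatrix with a scale wide enough."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values.reshape(-1, 1)
    lo = min(0.0, float(values.min()))
    hi = max(10.0, float(values.max()))
    scale = scale or ScaleSpec(lo, hi)
    ids = [f"S{i + 1}" for i in range(values.shape[0])]
    attrs = [f"M{j + 1}" for j in range(values.shape[1])]
    return ScoreMatrix(ids, attrs, values, scale)


@pytest.fixture(scope="session")
def random_similarity_closures():
    """200 (similarity, closure) pairs from random score tables."""
    rng = np.random.default_rng(777)
    out = []
    for _ in range(200):
        n = int(rng.integers(3, 13))
        m = int(rng.integers(2, 7))
        values = rng.uniform(0, 10, size=(n, m))
        sm = ScoreMatrix(
            [f"S{i}" for i in range(n)], [f"M{j}" for j in range(m)], values
        )
        s = similarity_matrix(sm)
        out.append((s, transitive_closure(s)))
    return out
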