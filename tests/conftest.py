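import numpy as np
import pytest

from graphmcdm import CriterionSpec, DecisionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(values, directions=None, alternatives=None):
    """Small DecisionMatrix factory for tests."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    m, n = values.shape
    if directions is None:
        directions = ["benefit"] * n
    alts = alternatives or [f"a{i+1}" for i in range(m)]
    crits = [CriterionSpec(f"c{j+1}", d) for j, d in enumerate(directions)]
    return DecisionMatrix(alts, crits, values)


@pytest.fixture
def positive_matrix(rng):
    """10x4 strictly positive decision matrix (well-conditioned)."""
    return make_matrix(rng.uniform(10, 100, size=(10, 4)))
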