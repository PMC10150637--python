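import numpy as np
import pytest

from svnsfuse import Polarity, ScoreMatrix, worked_example


@pytest.fixture(scope="session")
def example():
    """Packaged eight-image worked example: (true, false, truth labels)."""
    return worked_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def random_score_pair(rng):
    """Random paired true/false 8x8 score matrices."""

    def make(n=8, k=8, seed=None):
        local = rng if seed is None else np.random.default_rng(seed)
        order = tuple(f"C{j + 1}" for j in range(k))
        t = ScoreMatrix(local.uniform(size=(n, k)), Polarity.TRUE, order)
        f = ScoreMatrix(local.uniform(size=(n, k)), Polarity.FALSE, order)
        return t, f

    return make
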