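import numpy as np
import pytest

from chromarch import CircularGenome, ContactMatrix


@pytest.fixture
def genome20():
    """20 x 3 kb bins, circular."""
    return CircularGenome(60_000, 3000)


@pytest.fixture
def genome6():
    return CircularGenome(18_000, 3000)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_symmetric(B, rng, stage="raw", genome=None, positive=True):
    m = rng.random((B, B)) + (0.5 if positive else 0.0)
    m = m + m.T
    np.fill_diagonal(m, 0.0)
    g = genome if genome is not None else CircularGenome(B * 3000, 3000)
    return ContactMatrix(m, np.ones(B, dtype=bool), stage, g)


@pytest.fixture
def random_matrix_factory():
    return random_symmetric
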