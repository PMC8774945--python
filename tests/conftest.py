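import numpy as np
import pytest

from qsdlearn import (
    Distribution,
    SubMarkovKernel,
    loopy_chain,
    random_submarkov,
)


@pytest.fixture
def loopy01() -> SubMarkovKernel:
    return loopy_chain(0.1)


@pytest.fixture
def loopy05() -> SubMarkovKernel:
    return loopy_chain(0.5)


@pytest.fixture
def two_state() -> SubMarkovKernel:
    return SubMarkovKernel(np.array([[0.2, 0.6], [0.3, 0.4]]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_instance(n: int, seed: int) -> SubMarkovKernel:
    """A small random strictly sub-Markovian irreducible kernel."""
    rng = np.random.default_rng(seed)
    return random_submarkov(n, int(rng.integers(1, n + 1)), 0.7, seed=seed)


def random_distribution(n: int, seed: int) -> Distribution:
    rng = np.random.default_rng(seed)
    p = rng.random(n) + 0.05
    return Distribution(p / p.sum())
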