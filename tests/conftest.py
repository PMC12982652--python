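import numpy as np
import pytest

from entrochain import (
    StateSpace,
    simulate,
    reference_chain,
    validate_and_normalize,
)

MACROS = ("A", "B", "C", "D", "E")
MICROS = ("R", "W", "N", "F")


@pytest.fixture(scope="session")
def fixture_chain():
    """The packaged 20-state reference chain (row-normalized on load)."""
    return reference_chain()


@pytest.fixture(scope="session")
def long_run(fixture_chain):
    """One million simulated days of the reference chain, shared across tests."""
    return simulate(fixture_chain, 1_000_000, seed=20_260_927)


@pytest.fixture
def fair_coin_chain():
    return validate_and_normalize([[0.5, 0.5], [0.5, 0.5]], ["H", "T"])


@pytest.fixture
def cycle_chain():
    P = [[0, 1, 0], [0, 0, 1], [1, 0, 0]]
    return validate_and_normalize(P, ["a", "b", "c"])


@pytest.fixture
def uniform_block_chain():
    """Two macros, 4 micro each; every row uniform within its block + tiny leak."""
    space = StateSpace.uniform(("X", "Y"), MICROS)
    P = np.zeros((8, 8))
    P[:4, :4] = 0.99 / 4
    P[:4, 4:] = 0.01 / 4
    P[4:, 4:] = 0.99 / 4
    P[4:, :4] = 0.01 / 4
    return validate_and_normalize(P, space)


def random_stochastic(n, rng):
    """Dense random row-stochastic matrix (irreducible w.p. 1)."""
    M = rng.random((n, n)) + 1e-3
    return M / M.sum(1, keepdims=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
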