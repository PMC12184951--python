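import numpy as np
import pytest

from symsr import TransitionModel, circular_walk, grid_world

OPEN_5x5 = "#######\n" + "#.....#\n" * 5 + "#######"


@pytest.fixture(scope="session")
def biased_ring():
    """Clockwise-biased 6-state ring walk (non-reversible)."""
    return circular_walk(6, 0.2, 0.7, 0.1)


@pytest.fixture(scope="session")
def uniform_ring():
    return circular_walk(6, 1 / 3, 1 / 3, 1 / 3)


@pytest.fixture(scope="session")
def two_state():
    return TransitionModel(np.array([[0.5, 0.5], [0.2, 0.8]]))


@pytest.fixture(scope="session")
def open_grid_5x5():
    """5x5 open room: states, actions."""
    return grid_world(OPEN_5x5)


def random_ergodic_chain(rng, n):
    """Dense positive row-stochastic matrix: irreducible and aperiodic."""
    P = rng.random((n, n)) + 1e-3
    return TransitionModel(P / P.sum(axis=1, keepdims=True))
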