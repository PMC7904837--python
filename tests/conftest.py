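import numpy as np
import pytest

from trajdmi import (
    DiscreteEnsemble,
    HiddenMarkovModel,
    TrajectoryEnsemble,
)
from trajdmi.models import _random_stochastic


def random_hmm(n_hidden: int, n_symbols: int, seed: int) -> HiddenMarkovModel:
    rng = np.random.default_rng(seed)
    return HiddenMarkovModel(
        pi=rng.dirichlet(np.ones(n_hidden)),
        T=_random_stochastic(rng, (n_hidden, n_hidden)),
        E=_random_stochastic(rng, (n_symbols, n_hidden)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_hmm():
    """Random 3-hidden / 3-symbol model for oracle comparisons."""
    return random_hmm(3, 3, seed=17)


@pytest.fixture
def two_condition_ensembles(rng):
    """Two small continuous ensembles with different means."""
    a = TrajectoryEnsemble("condA", rng.normal(1.0, 0.3, size=(20, 12)), time_step=5.0)
    b = TrajectoryEnsemble("condB", rng.normal(2.0, 0.3, size=(20, 12)), time_step=5.0)
    return [a, b]


@pytest.fixture
def tiny_discrete():
    states = np.array([[0, 1, 0], [1, 1, 0], [0, 0, 1], [1, 0, 1]])
    return DiscreteEnsemble("tiny", states, n_symbols=2, scheme_id="tiny")
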