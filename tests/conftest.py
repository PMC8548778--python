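import numpy as np
import pytest

from corthick.neuralnet import MLPModel
from corthick.training import LMConfig, SAConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fast_sa():
    """Shortened annealing schedule for unit tests."""
    return SAConfig(n_temperatures=20, iters_per_temperature=20)


@pytest.fixture
def lm():
    return LMConfig()


def random_model(rng, n_hidden, scale=0.8):
    p = 2 if n_hidden == 0 else 3 * n_hidden + 1
    return MLPModel.zeros(n_hidden).with_params(rng.uniform(-scale, scale, p))
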