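import numpy as np
import pytest

from dichrel import (
    ItemBank,
    make_grid,
    sample_item_parameters,
    sample_theta,
    simulate_responses,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bank15(rng):
    """A 15-item bank drawn from the standard generating distributions."""
    return sample_item_parameters(15, rng)


@pytest.fixture
def grid101():
    return make_grid(101, -6.0, 6.0)


@pytest.fixture
def responses_500(bank15, rng):
    """N=500 response matrix simulated from bank15."""
    theta = sample_theta(500, rng=rng)
    return simulate_responses(theta, bank15, rng)


@pytest.fixture
def toy_alpha_matrix():
    """4 persons x 3 items; alpha = 0.75 by hand computation."""
    return np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=np.int8)


@pytest.fixture
def strong_bank():
    """Highly discriminating homogeneous items (high reliability)."""
    return ItemBank(a=np.full(20, 1.5), b=np.zeros(20))
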