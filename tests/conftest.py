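import numpy as np
import pytest

from kinsim import compile_model, fixtures


@pytest.fixture
def chain2():
    return fixtures.two_step_chain()


@pytest.fixture
def chain2_exec(chain2):
    return compile_model(chain2)


@pytest.fixture
def closed_pair_exec():
    return compile_model(fixtures.closed_pair())


@pytest.fixture
def mm_exec():
    return compile_model(fixtures.michaelis_menten())


def deterministic_fixture_models():
    """The deterministic test corpus used by cross-integrator checks."""
    return [
        fixtures.two_step_chain(),
        fixtures.closed_pair(),
        fixtures.michaelis_menten(),
        fixtures.bistable_switch(),
        fixtures.linear_chain(3, seed=11),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
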