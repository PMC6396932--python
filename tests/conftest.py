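import numpy as np
import pytest

from hsckinetics.model import ModelKind
from hsckinetics.simulate import ExchangeSchedule, simulate
from hsckinetics.synthetic import default_params


@pytest.fixture(scope="session")
def three_params():
    return default_params(ModelKind.three_state)


@pytest.fixture(scope="session")
def five_params():
    return default_params(ModelKind.five_state)


@pytest.fixture(scope="session")
def sched_2d():
    return ExchangeSchedule(frequency=2.0)


@pytest.fixture(scope="session")
def traj3_default(three_params, sched_2d):
    """The calibrated default three-state run, shared across tests."""
    return simulate(ModelKind.three_state, three_params, sched_2d)


@pytest.fixture(scope="session")
def traj5_default(five_params, sched_2d):
    return simulate(ModelKind.five_state, five_params, sched_2d)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
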