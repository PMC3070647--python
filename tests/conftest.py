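import numpy as np
import pytest

import ipsa as ip
from ipsa.fixtures import load_fixture_config


@pytest.fixture(scope="session")
def decay_model():
    """dx/dt = -k x, k = 1, x0 = 1 (k-parameterization, closed forms known)."""
    return ip.build_model(load_fixture_config("linear_decay"))


@pytest.fixture(scope="session")
def linear2():
    """Diagonal linear system with analytic sensitivity callables."""
    model, analytic = ip.make_linear_model([-1.0, -2.0], [1.0, 0.5])
    return model, analytic


@pytest.fixture(scope="session")
def switch_model():
    return ip.make_simple_network()


@pytest.fixture(scope="session")
def switch_traj(switch_model):
    return ip.simulate(switch_model)


@pytest.fixture(scope="session")
def switch_time(switch_traj):
    return ip.switching_time(switch_traj, "x6")


@pytest.fixture(scope="session")
def random_mm_10():
    return ip.make_random_mm(seed=7, n_states=10)


def grid(t0, t1, n):
    return np.linspace(t0, t1, n)
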