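import numpy as np
import pytest

from hetsnn import (
    NetworkSpec,
    NeuronParams,
    default_params,
    init_network_params,
)
from hetsnn.synthetic import gen_temporal_classes


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def temporal_dataset():
    """The packaged 3-class spike-timing task (2 neurons, T=5)."""
    X, y, side = gen_temporal_classes(n_classes=3, neurons=2, T=5, jitter=0.1, n_per_class=40, seed=7)
    return X, y, side


@pytest.fixture
def small_net():
    spec = NetworkSpec([2, 3, 2], time_steps=2, readout="membrane-accumulate")
    params = init_network_params(spec, seed=1, alpha_jitter_sd=0.1)
    return spec, params


@pytest.fixture
def truth_params():
    return NeuronParams(tau=0.3, gamma=0.5, C=1.0, u_th=1.0, u_re=0.0)


def scalar_reference_step(u, o_prev, S, tau, gamma, C, u_th, u_re, slope=0.01):
    """Independent plain-Python oracle for one neuron update (no numpy ops)."""
    I = S - gamma * o_prev
    a = (1.0 - tau) * u + tau * u_re + C * I
    u_pre = a if a >= 0 else slope * a
    O = 1.0 if (u_pre - u_th) > 0 else 0.0
    u_post = (1.0 - O) * u_pre + O * u_re
    return u_post, O, u_pre
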