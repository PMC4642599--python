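import numpy as np
import pytest

from sigreach import generate_instance, generate_network


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_instance(rng, n_nodes=8, n_edges=10, n_sources=2, n_targets=2, noise_sd=0.0):
    """A random DAG instance with ground-truth probabilities and clean C."""
    net = generate_network(n_nodes, n_edges, n_sources, n_targets, rng)
    return generate_instance(net, noise_sd, rng)


@pytest.fixture
def small_instance(rng):
    return random_instance(rng)
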