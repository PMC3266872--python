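import numpy as np
import pytest

from embednet import netgen


@pytest.fixture(scope="session")
def toy():
    return netgen.build_toy_network()


@pytest.fixture(scope="session")
def hub_network():
    return netgen.build_modular_hub_network(seed=3)


def random_digraph(rng, n_min=5, n_max=40, p_min=0.05, p_max=0.5):
    """A random simple digraph for oracle comparisons."""
    n = int(rng.integers(n_min, n_max + 1))
    p = rng.uniform(p_min, p_max)
    hit = rng.random((n, n)) < p
    np.fill_diagonal(hit, False)
    edges = np.column_stack(np.nonzero(hit))
    return netgen.DirectedNetwork(n, edges, np.zeros(n, dtype=np.int8))
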