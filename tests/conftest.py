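import numpy as np
import pytest

import netmood as nm


@pytest.fixture(scope="session")
def strong_planted():
    """Edge-level dataset with a strong planted rank-1 signal (d=10, n=100)."""
    cfg = nm.SimConfig(n_sessions=100, n_nodes=20, signal_strength=10.0, seed=11)
    edges, mood, truth = nm.generate_edge_dataset(cfg)
    return edges, mood, truth


@pytest.fixture(scope="session")
def null_planted():
    """Edge-level dataset with no planted signal (d=0, n=73)."""
    cfg = nm.SimConfig(n_sessions=73, n_nodes=10, signal_strength=0.0, seed=12)
    edges, mood, truth = nm.generate_edge_dataset(cfg)
    return edges, mood, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def random_fc(rng):
    """A valid random 8-node FC matrix (correlations of random series)."""
    ts = rng.standard_normal((120, 8))
    return nm.fc_matrix(ts)
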