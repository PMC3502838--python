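import numpy as np
import pytest

from ecgi.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced forward dataset shared across tests (30 leads x 40 nodes,
    full 358-instant protocol)."""
    return simulate_dataset(SimulationConfig(n_leads=30, n_nodes=40, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_blobs_2d(rng, centers, n_per, spread=1.0):
    """Isotropic Gaussian blobs with known generative labels."""
    centers = np.asarray(centers, dtype=float)
    X = np.vstack([rng.normal(c, spread, size=(n_per, centers.shape[1]))
                   for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return X, labels
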