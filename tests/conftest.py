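import numpy as np
import pytest

from gmlsort.simulate import SimulationConfig, generate_dataset, make_qgrid


@pytest.fixture
def qgrid():
    """Small detector: 64x64, 4-row gap, 70 nm particle."""
    return make_qgrid(64, 64, 0.11, gap_rows=4, particle_diameter=70.0)


@pytest.fixture
def qgrid_nogap():
    return make_qgrid(64, 64, 0.11, gap_rows=0, particle_diameter=70.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_noise_free_sets():
    """Matched noise-free train/test sets, small enough for fast tests."""
    cfg = SimulationConfig(n_train=300, n_test=300, n_rows=64, n_cols=64, noise_free=True)
    train = generate_dataset(cfg, n=300, seed=101, noise_free=True)
    test = generate_dataset(cfg, n=300, seed=202, noise_free=True)
    return train, test


@pytest.fixture(scope="session")
def two_cluster_features():
    """Two overlapping Gaussian clusters with binary labels (n=80, p=6).

    Separated enough to classify, close enough that the kNN graph
    stays connected (so the leading eigenvector is quasi-constant).
    """
    rng = np.random.default_rng(7)
    a = rng.normal(0.0, 0.8, size=(45, 6))
    b = rng.normal(1.1, 0.8, size=(35, 6))
    X = np.vstack([a, b])
    f = np.concatenate([np.ones(45, dtype=int), np.zeros(35, dtype=int)])
    perm = rng.permutation(80)
    return X[perm], f[perm]
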