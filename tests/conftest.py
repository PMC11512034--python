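import numpy as np
import pandas as pd
import pytest

import spicevision as sv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blobs_table():
    """Five well-separated Gaussian blobs in 2 features, 20 samples each."""
    g = np.random.default_rng(77)
    centers = np.array([[0, 0], [4, 0], [0, 4], [4, 4], [2, 2]], dtype=float)
    X = g.standard_normal((100, 2)) * 0.3 + centers.repeat(20, axis=0)
    labels = np.repeat([1, 2, 3, 4, 5], 20)
    return sv.FeatureTable(
        features=pd.DataFrame(X, columns=["a", "b"]), labels=labels)


@pytest.fixture
def informative_table():
    """One feature tracking the class index plus nine pure-noise features."""
    g = np.random.default_rng(0)
    labels = np.repeat([1, 2, 3, 4, 5], 12)
    X = g.standard_normal((60, 10))
    X[:, 3] = labels + g.standard_normal(60) * 0.05
    return sv.FeatureTable(
        features=pd.DataFrame(X, columns=[f"f{i}" for i in range(10)]),
        labels=labels)


@pytest.fixture(scope="session")
def small_image_set():
    """A quick low-resolution simulated campaign shared across tests."""
    cfg = sv.SimConfig(images_per_level=4, image_size=(64, 64), seed=11)
    return sv.generate_dataset(sv.BLACK_PEPPER, sv.SEA_FOAM, cfg)
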