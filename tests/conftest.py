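import numpy as np
import pytest

from bcdnet import features, synthetic_data
from bcdnet.optimizers import SearchSpace


def sphere(x):
    return float(np.sum(np.square(x)))


@pytest.fixture(scope="session")
def sphere_space():
    return SearchSpace(lower=-5.0 * np.ones(6), upper=5.0 * np.ones(6))


@pytest.fixture(scope="session")
def phantom_set():
    """Small deterministic phantom set shared across tests."""
    return synthetic_data.generate_phantoms(
        synthetic_data.PhantomSpec(n_per_class=(15, 15, 15), seed=11)
    )


@pytest.fixture(scope="session")
def tiny_features(phantom_set):
    """Deep features of the shared phantom set through the tiny backbone."""
    backbone = features.VGGBackbone(features.BackboneConfig(tiny_mode=True, seed=11))
    batch = features.preprocess_images(
        list(phantom_set.images), 64, phantom_set.labels
    )
    return features.extract_deep_features(batch, backbone=backbone)


@pytest.fixture(scope="session")
def separable_features():
    """Two well-separated Gaussian classes in 32 dimensions."""
    rng = np.random.default_rng(5)
    n = 60
    labels = np.repeat([0, 1], n // 2)
    centers = np.stack([np.zeros(32), np.full(32, 3.0)])
    values = centers[labels] + rng.normal(scale=0.5, size=(n, 32))
    return values, labels
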