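import numpy as np
import pytest

from leafensemble.classification import CoAtNetConfig, EnhancedCoAtNetConfig
from leafensemble.synthetic import DatasetSpec, generate_leaf_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 well-separated classes, 30 images each, 64 px."""
    spec = DatasetSpec(n_classes=3, images_per_class=30, image_size=64, seed=7)
    return generate_leaf_dataset(spec)


@pytest.fixture(scope="session")
def tiny_coatnet_config():
    return CoAtNetConfig(stage_layout=("conv", "conv", "transformer"),
                         channels=(8, 16, 32), blocks_per_stage=(1, 1, 1),
                         n_heads=4, n_classes=3, input_size=64)


@pytest.fixture(scope="session")
def tiny_enhanced_config(tiny_coatnet_config):
    return EnhancedCoAtNetConfig(base=tiny_coatnet_config, n_scales=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def numeric_gradient(f, x, eps=1e-3):
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
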