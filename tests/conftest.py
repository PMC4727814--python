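import numpy as np
import pytest

from citrusbrix import (
    DatasetSimConfig,
    ImageSimConfig,
    average_images,
    gen_citrus_image,
    gen_feature_dataset,
)


@pytest.fixture(scope="session")
def default_scene():
    """Default synthetic citrus scene: (replicate stack, truth mask, config)."""
    cfg = ImageSimConfig(seed=1)
    stack, truth = gen_citrus_image(cfg)
    return stack, truth, cfg


@pytest.fixture(scope="session")
def averaged_image(default_scene):
    stack, _, _ = default_scene
    return average_images(stack)


@pytest.fixture(scope="session")
def small_scene():
    """A small scene for brute-force comparisons (<= 64x64)."""
    cfg = ImageSimConfig(height=48, width=64, center=(24, 32), axes=(15, 20), seed=7)
    stack, truth = gen_citrus_image(cfg)
    return average_images(stack), truth, cfg


@pytest.fixture(scope="session")
def ratio_dataset():
    """Default ratio-form dataset at the default noise level."""
    return gen_feature_dataset(DatasetSimConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
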