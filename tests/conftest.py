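import numpy as np
import pytest

from ldcnet import ModelConfig, SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A narrow model that exercises every architectural path cheaply."""
    return ModelConfig(stem_channels=4, growth_rates=(2, 2, 2, 2),
                       fpn_channels=8, level_channels=2, num_classes=3,
                       ccam_reduction=4, seed=0)


@pytest.fixture
def small_scene_batch():
    """Six 64x64 scenes with two instrument classes, as model-ready arrays."""
    images, masks = [], []
    for i in range(6):
        cfg = SceneConfig(image_size=64, min_instrument_width=4,
                          max_instrument_width=8, seed=500 + i)
        img, msk = generate_scene(cfg)
        images.append(img.transpose(2, 0, 1))
        masks.append(msk.astype(np.int64))
    return np.stack(images), np.stack(masks)
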