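import numpy as np
import pytest

import leafvit as lv


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_cfg():
    """2-layer, 4x4-token model: fast enough for exhaustive numeric checks."""
    return lv.ModelConfig(
        image_size=16, patch_size=4, embed_dim=8, num_heads=2, num_layers=2,
        drop_path_rate=0.0, dropout_rate=0.0, region_grid=2, routing_k=2,
    )


@pytest.fixture(scope="session")
def leaf_batch():
    """50 images per class from the default generator (seeded)."""
    spec = lv.LeafImageSpec()
    images, labels = [], []
    for ci, cls in enumerate(lv.CLASS_NAMES):
        gen = np.random.default_rng(np.random.SeedSequence((0, ci)))
        for _ in range(50):
            img, _ = lv.generate_leaf_image(cls, spec, gen)
            images.append(img)
            labels.append(ci)
    return np.stack(images), np.asarray(labels)
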