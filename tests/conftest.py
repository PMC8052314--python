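import numpy as np
import pytest

from ampulla import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """60 tiny synthetic images with fully informative difficulty features."""
    cfg = SynthConfig(n_images=60, image_size=32, seed=7, difficulty_feature_strength=1.0)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
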