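import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ftuseg

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """8 glomeruli on a 512 px desk-scale canvas at 4 µm/px."""
    spec = ftuseg.SceneSpec(seed=7, image_shape=(512, 512), n_ftu=8)
    return ftuseg.generate_scene(spec)


def random_binary_mask(rng, shape=(24, 31), p=0.3):
    return ftuseg.BinaryMask(rng.random(shape) < p)
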