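import numpy as np
import pytest

from ihcloc import StainModel, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny seeded dataset shared by read-only tests."""
    return generate_dataset(6, 1, 0.0, image_size=(48, 48), seed=7)


@pytest.fixture(scope="session")
def noiseless_stain():
    return StainModel(noise_sd=0.0)


def random_gray_images(n, shape=(6, 6), seed=0, levels=256):
    """Integer-valued gray images on the [0,1] scale (exact u8 grid)."""
    g = np.random.default_rng(seed)
    return [g.integers(0, levels, size=shape) / 255.0 for _ in range(n)]
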