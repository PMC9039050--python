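import numpy as np
import pytest

from toothmark.synthetic import SyntheticParams, generate_samples


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """A small balanced synthetic dataset shared across read-only tests."""
    return generate_samples(8, 10, SyntheticParams(), seed=42)


@pytest.fixture
def rectangle_image():
    """The filled-rectangle fixture: x in [62, 162), y in [32, 192) on 224x224."""
    img = np.zeros((224, 224, 3), dtype=np.uint8)
    img[32:192, 62:162] = 200
    return img
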