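import numpy as np
import pytest

from mnattnet import build_model, generate_dataset


@pytest.fixture(scope="session")
def tiny_model():
    """One randomly initialized model shared by read-only forward-pass tests."""
    return build_model(init_seed=7)


@pytest.fixture(scope="session")
def small_batch():
    """A small normalized batch of synthetic frames (2 pos, 2 neg)."""
    imgs = generate_dataset(2, 2, seed=11)
    x = np.stack([im.pixels for im in imgs])
    y = np.array([im.label for im in imgs])
    return x, y


@pytest.fixture(scope="session")
def image_pool():
    """A reusable pool of rendered frames for pipeline tests."""
    return generate_dataset(6, 14, seed=5)
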