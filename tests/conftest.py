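import numpy as np
import pytest

from shl.coding import build_gram
from shl.images import ImageSet, SyntheticParams, synthesize_images


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dictionary(rng):
    """Random 8-atom dictionary in M=16 dimensions."""
    return build_gram(rng.standard_normal((8, 16)))


@pytest.fixture(scope="session")
def tiny_images():
    """A small synthetic image set shared across tests."""
    return synthesize_images(
        SyntheticParams(n_images=4, image_size=64, n_edges=8, seed=7)
    )
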