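import numpy as np
import pytest

from drfusion.synthetic import SynthSpec, generate_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_rgb(rng):
    """A seeded 32x32 RGB image away from the clipping limits."""
    return rng.uniform(0.05, 0.95, (32, 32, 3))


@pytest.fixture
def random_gray(rng):
    return rng.uniform(0.0, 1.0, (16, 16))


@pytest.fixture(scope="session")
def small_corpus():
    """20 images per class at 96x96: shared across feature/model tests."""
    return generate_corpus(SynthSpec(n_per_class=20, image_size=96, seed=7))
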