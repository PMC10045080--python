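import numpy as np
import pytest

from histofusion.synthetic import default_class_specs, generate_image


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def class_specs():
    return default_class_specs(1.0)


@pytest.fixture(scope="session")
def sample_images(class_specs):
    """One 64x64 image per synthetic class, fixed seeds."""
    return [generate_image(spec, 64, seed=100 + i)
            for i, spec in enumerate(class_specs)]


@pytest.fixture()
def random_uint8_image(rng):
    return rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
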