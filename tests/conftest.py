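import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_images():
    """50 seeded random 8x8 gray-value images for oracle suites."""
    gen = np.random.default_rng(2024)
    return [gen.random((8, 8)) * 255 for _ in range(50)]
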