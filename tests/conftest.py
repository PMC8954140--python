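import numpy as np
import pytest

from lgeseg.io import LabelMap
from lgeseg.phantom import PhantomSpec, generate_case


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom_case():
    """One deterministic scar+MVO phantom (volume, labels, patient)."""
    return generate_case(PhantomSpec(seed=7))


@pytest.fixture
def random_labelmap(rng):
    """Factory for random small label maps (all 5 classes possible)."""

    def make(shape=(12, 12, 6), seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return LabelMap(r.integers(0, 5, size=shape), spacing=(1.0, 1.0, 2.0))

    return make
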