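import numpy as np
import pytest

from retivess.phantom import PhantomSpec, generate_phantom
from retivess.types import FundusImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_fundus(rng):
    """A 64x64 random color image wrapped as a FundusImage."""
    px = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
    return FundusImage(pixels=px)


@pytest.fixture
def mixed_phantom():
    """One mid-size phantom with vessels of mixed width and its gold mask."""
    spec = PhantomSpec(shape=(256, 256), n_vessels=4, width_range=(2.0, 16.0), seed=11)
    return generate_phantom(spec)
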