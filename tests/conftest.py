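import numpy as np
import pytest
from hypothesis import settings

from soilkrige import Region, VariogramModel

settings.register_profile("soilkrige", derandomize=True, deadline=None, max_examples=40)
settings.load_profile("soilkrige")


@pytest.fixture
def unit_square():
    return Region.rectangle(0.0, 0.0, 1.0, 1.0)


@pytest.fixture
def km_square():
    """8 km x 8 km study region, comfortably larger than the Pb range."""
    return Region.rectangle(0.0, 0.0, 8000.0, 8000.0)


@pytest.fixture
def pb_model():
    """Log-scale spherical model typical of urban soil Pb."""
    return VariogramModel("spherical", nugget=0.047, partial_sill=0.133, range_m=2263.3)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def scatter(n, extent, seed):
    """Seeded uniform point scatter used by several oracles."""
    r = np.random.default_rng(seed)
    return r.uniform(0, extent, (n, 2))
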