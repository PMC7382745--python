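import numpy as np
import pytest

from mdunet import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default-parameter phantom, shared read-only across tests."""
    return generate_phantom(PhantomParams(seed=7))


@pytest.fixture(scope="session")
def small_phantom():
    """A 64x64 phantom for cheap pipeline tests."""
    return generate_phantom(PhantomParams(height=64, width=64, n_rib_pairs=3,
                                          rib_band_width=3, clavicle_thickness=3, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
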