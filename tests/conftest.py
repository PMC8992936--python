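import numpy as np
import pytest

from posequiv import PhantomSpec, make_phantom, make_ptv


@pytest.fixture(scope="session")
def small_spec():
    """Coarse phantom for fast registration tests (48^3 at 4 mm)."""
    return PhantomSpec(grid_shape=(48, 48, 48), spacing=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_phantom(small_spec)


@pytest.fixture(scope="session")
def default_phantom():
    """Phantom at the default clinical-like resolution."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def sphere_ptv():
    return make_ptv(center=(0.0, -5.0, -35.0), semi_axes=(20.0, 20.0, 20.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
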