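import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import breastdwi as bd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def quad_scheme():
    return bd.AcquisitionScheme(bd.DEFAULT_QUADRUPLE)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom_spec():
    """A reduced phantom for fast end-to-end tests."""
    return bd.PhantomSpec(shape=(20, 20, 8),
                          lesion_centers=((7.0, 7.0, 4.0),),
                          lesion_radii=(3.5,),
                          rim_thickness=1.5,
                          seed=7)
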