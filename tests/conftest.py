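import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fusmark as fm

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geom() -> fm.TransducerGeometry:
    """The study transducer: 1 MHz, 13 cm focal length, 15.4 cm aperture."""
    return fm.TransducerGeometry()


@pytest.fixture(scope="session")
def bowl_planes(geom):
    """Noiseless 41x41, 0.5 mm scan planes at the focus and +/-6 mm.

    Session-scoped: the Rayleigh integral at full source discretization is
    the expensive part of the suite and several tests share these planes.
    """
    return {
        dz: fm.simulate_bowl_plane(geom, n=41, spacing=0.5e-3, z_offset=dz)
        for dz in (0.0, -6e-3, 6e-3)
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
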