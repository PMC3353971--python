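import numpy as np
import pytest
from hypothesis import settings

import nucspat as ns

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def unit_sphere():
    return ns.PiecewiseEllipsoidRegion(ns.HalfAxisParams(1, 1, 1, 1, 1, 1))


@pytest.fixture(scope="session")
def ellipsoid():
    """Sphere extruded along +x (a_plus = 2)."""
    return ns.PiecewiseEllipsoidRegion(ns.HalfAxisParams(2, 1, 1, 1, 1, 1))


@pytest.fixture(scope="session")
def flat_sphere():
    """Sphere flattened on the underside (c_minus = 0.5)."""
    return ns.PiecewiseEllipsoidRegion(ns.HalfAxisParams(1, 1, 1, 1, 1, 0.5))
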