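import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from azogate.synthetic_data import ScaffoldSpec, make_toy_dimer, make_toy_lbd
from azogate.toy_system import build_azobenzene

settings.register_profile(
    "ci", max_examples=50, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def minimal_model():
    return build_azobenzene("minimal")


@pytest.fixture(scope="session")
def phenyl_model():
    return build_azobenzene("phenyl")


@pytest.fixture(scope="session")
def scaffold():
    return make_toy_lbd(ScaffoldSpec())


@pytest.fixture(scope="session")
def dimer():
    return make_toy_dimer(ScaffoldSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    """Uniform proper rotation matrix (QR of a Gaussian matrix, det fixed)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
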