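import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hippaxes.acquisition import multishell_scheme
from hippaxes.synthetic import make_voxel_domain

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def full_scheme():
    """HCP-like scheme: 18 b=0 + 90 directions at b = 1000/2000/3000."""
    return multishell_scheme()


@pytest.fixture(scope="session")
def small_scheme():
    """Reduced multi-shell scheme for fast fitting tests."""
    return multishell_scheme(n_dirs=30, n_b0=6)


@pytest.fixture(scope="session")
def slab_domain():
    return make_voxel_domain((16, 16, 8), "slab")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
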