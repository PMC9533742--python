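import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scattergap.geometry import PILATUS3_2M, build_full_mask, rescale_mask

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def pilatus_mask():
    return build_full_mask(PILATUS3_2M)


@pytest.fixture(scope="session")
def mask512(pilatus_mask):
    return rescale_mask(pilatus_mask, 512, 512)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
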