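import numpy as np
import pytest

from censoc.pools import DecompParams, SiteProfile
from censoc.sites import get_site


@pytest.fixture
def loam() -> SiteProfile:
    """The reference loam texture (modifier normalization point)."""
    return SiteProfile(sand=0.4, silt=0.4, clay=0.2, ph=7.0, bulk_density=1.4)


@pytest.fixture
def params() -> DecompParams:
    return DecompParams()


@pytest.fixture
def neutral_params() -> DecompParams:
    """Nominal DEFAC=1 parameterization with the slow pool as 25-yr turnover."""
    return DecompParams.from_turnover(25.0, defac_reference=1.0)


@pytest.fixture
def changping():
    return get_site("changping")


@pytest.fixture
def yangling():
    return get_site("yangling")


@pytest.fixture
def qiyang():
    return get_site("qiyang")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240421)
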