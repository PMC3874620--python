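import pytest
from hypothesis import settings

from fortiplan import default_parameters, default_trajectory

settings.register_profile("deterministic", derandomize=True, max_examples=100)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    """Packaged published defaults (German consumption survey, IOM/DGE targets)."""
    return default_parameters()


@pytest.fixture(scope="session")
def trajectory():
    """Default calibrated baseline: mean 45 nmol/L, trough 27.8 nmol/L in January."""
    return default_trajectory()
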