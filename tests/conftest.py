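import pytest
from hypothesis import HealthCheck, settings

from polyerode import load_parameter_set

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def plla():
    """PLLA parameter set calibrated at 50 C (the package default)."""
    return load_parameter_set("plla_50c")


@pytest.fixture(scope="session")
def plga():
    """PLGA literature parameter set (strong autocatalysis)."""
    return load_parameter_set("plga_literature")
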