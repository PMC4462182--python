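import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rieskeq import seqcore

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_panel():
    """The packaged clade-specific dioxygenase primer panel (18 oligos)."""
    return seqcore.load_reference_panel()


@pytest.fixture(scope="session")
def reference_curves():
    """Published standard-curve coefficients for the reference panel."""
    return seqcore.load_reference_standard_curves()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
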