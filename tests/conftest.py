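import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def strict_pwm():
    """Sharp G-box PWM used across motif/spacing tests."""
    from lck.motifs import build_pwm

    return build_pwm(["CACGTG"] * 20, pseudocount=0.1, name="GBOX")
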