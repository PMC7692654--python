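import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# deterministic property testing: same example sequence on every run
settings.register_profile(
    "thermokin",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("thermokin")


@pytest.fixture()
def rng():
    return np.random.default_rng(20201103)
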