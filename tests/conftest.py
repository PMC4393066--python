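import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def halting_model():
    """The packaged halting model (quantile 0.95, min_len 3000)."""
    from isoseg.halting import default_halting_model

    return default_halting_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230415)
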