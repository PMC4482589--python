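import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_dataset():
    """A seeded constant-relationship dataset (climate, ln-area response)."""
    import fireshift as fs
    climate, area, truth = fs.generate_scenario(fs.constant_spec(seed=7))
    return climate, fs.log_transform_area(area), truth
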