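import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_study():
    """Six small synthetic slides (3 positive / 3 negative) shared across tests."""
    import slidestream as ss

    return ss.generate_study(
        6, nodes_per_slide=1, lesion_mix={"none": 0.5, "micro": 0.5}, canvas=256, seed=42
    )
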