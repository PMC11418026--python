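import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def setup_65():
    from salticid_vision.geometry import MonitorSetup

    return MonitorSetup(537.0, 65.0, 200.0)


@pytest.fixture
def setup_120():
    from salticid_vision.geometry import MonitorSetup

    return MonitorSetup(537.0, 120.0, 200.0)


@pytest.fixture
def walker_spec():
    from salticid_vision.stimuli import StimulusSpec

    return StimulusSpec(seed=42)
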