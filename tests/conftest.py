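import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """One planted default study (200 neurons, 5 patterns, 10 reps/pattern)."""
    from assemblyscope.circuit import default_study

    return default_study(seed=11, reps_per_pattern=10)


@pytest.fixture(scope="session")
def detected(small_study):
    """Assemblies detected on the small study with default settings."""
    from assemblyscope.detect import DetectConfig, detect

    return detect(small_study.spikes, small_study.stream, DetectConfig(seed=0))
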