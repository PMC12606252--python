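import pytest
from hypothesis import HealthCheck, settings

from breakaway import RaceScenario, default_scenario

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def scenario() -> RaceScenario:
    """Canonical flat-stage scenario used throughout the worked examples."""
    return default_scenario()
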