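import pytest
from hypothesis import HealthCheck, settings

from shpt_cea import ModelConfig, ScenarioSpec, paper_fixture, random_scenario

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_config() -> ModelConfig:
    """The packaged transcription of the published parameter tables."""
    return paper_fixture()


@pytest.fixture()
def scenario_config() -> ModelConfig:
    """One representative random scenario."""
    return random_scenario(ScenarioSpec(seed=42))
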