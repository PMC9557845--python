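import hypothesis
import pytest

from changesim import build_all_scenarios, build_scenario

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenarios():
    """All eight scenarios under the default calibration."""
    return build_all_scenarios()


@pytest.fixture(scope="session")
def scenario_1a():
    return build_scenario("1A")


@pytest.fixture(scope="session")
def scenario_2a():
    return build_scenario("2A")


@pytest.fixture(scope="session")
def scenario_3a():
    return build_scenario("3A")
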