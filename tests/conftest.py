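import pytest
from hypothesis import HealthCheck, settings

import childimpact as ci

settings.register_profile(
    "package",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def worked_scenario() -> ci.Scenario:
    return ci.make_worked_examples()


@pytest.fixture(scope="session")
def random_scenario() -> ci.Scenario:
    return ci.make_random_country(ci.FixtureSpec(seed=1))
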