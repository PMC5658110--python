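import pytest

from mddcea import ScenarioSpec, generate_distributions, generate_parameter_set


@pytest.fixture(scope="session")
def anchored_ps():
    """Paper-anchored mid-50s scenario (16-year likely horizon)."""
    return generate_parameter_set(ScenarioSpec(seed=0, cohort="mid-50s"))


@pytest.fixture(scope="session")
def anchored_dist_ps():
    """Same scenario with moment-matched distributions on every parameter."""
    return generate_distributions(ScenarioSpec(seed=0, cohort="mid-50s"))
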