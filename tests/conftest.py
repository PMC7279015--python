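import pytest
from hypothesis import HealthCheck, settings

from strainsnp.filtering import filter_group, union_across_groups
from strainsnp.simulate import (
    default_scenario,
    generate_reference,
    generate_sample_calls,
    generate_strain_panel,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=1)


@pytest.fixture(scope="session")
def reference(scenario):
    return generate_reference(scenario)


@pytest.fixture(scope="session")
def panel_and_truth(scenario, reference):
    return generate_strain_panel(reference, scenario)


@pytest.fixture(scope="session")
def panel(panel_and_truth):
    return panel_and_truth[0]


@pytest.fixture(scope="session")
def truth(panel_and_truth):
    return panel_and_truth[1]


@pytest.fixture(scope="session")
def calls(scenario, reference, truth):
    return generate_sample_calls(reference, truth, scenario)


@pytest.fixture(scope="session")
def filtered_union(scenario, calls):
    per_group = [filter_group(calls[g], g) for g in scenario.groups]
    return union_across_groups(per_group)
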