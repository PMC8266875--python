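import pytest
from hypothesis import HealthCheck, settings

# One deterministic hypothesis profile for the whole suite.
settings.register_profile(
    "fluorisk",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("fluorisk")

SEED = 0


@pytest.fixture(scope="session")
def reference_summaries():
    from fluorisk import reference_group_summaries

    return reference_group_summaries()


@pytest.fixture(scope="session")
def water_profiles():
    from fluorisk import reference_water_profiles

    return reference_water_profiles()


@pytest.fixture(scope="session")
def infusible_means():
    from fluorisk import reference_infusible_means_by_water

    return reference_infusible_means_by_water()
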