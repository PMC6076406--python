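import pytest
from hypothesis import settings

from nutledger.availability import aggregate_availability

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from nutledger.synthetic_world import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_config():
    return WorldConfig(
        n_items=30,
        n_locations=15,
        year_start=2000,
        year_end=2009,
        n_super_regions=3,
        missing_fraction=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def small_panel(small_world):
    """Availability panel aggregated from the observed supply rows."""
    return aggregate_availability(
        small_world.supply, small_world.composition, small_world.matching
    )


@pytest.fixture(scope="session")
def complete_panel(small_world):
    """Ground-truth availability panel with no missingness."""
    return small_world.ground_truth.true_availability_panel
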