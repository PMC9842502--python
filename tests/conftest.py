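import pytest
from hypothesis import HealthCheck, settings

from croplandn.budget import RegionBudget, TargetSpec
from croplandn.synthetic import SyntheticConfig, generate_world

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def toy_budget():
    """Round-number closed budget: input 100, harvest 40, losses 60."""
    return RegionBudget(
        region="T",
        n_fer=50.0, n_man=20.0, n_fix=10.0, n_dep=10.0, n_irr=10.0,
        n_harvest=40.0,
        e_nh3=15.0, e_n2o=3.0, e_nox=2.0, e_n2=10.0,
        n_leach=20.0, n_runoff=10.0,
        area=100.0,
    )


@pytest.fixture
def toy_target():
    # High enough that the NUE cap does not truncate the measure set.
    return TargetSpec(region="T", nue_target=0.9, target_harvest=60.0)


@pytest.fixture(scope="session")
def small_world():
    """A small but complete synthetic study, shared read-only."""
    return generate_world(
        SyntheticConfig(seed=11, n_regions=4, n_obs_per_cell=6, obs_noise_sd=0.2)
    )
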