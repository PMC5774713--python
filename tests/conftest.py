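import pytest

from smallholder import InitConfig, ScenarioConfig
from smallholder.landscape import Landscape, generate_landscape
from smallholder.engine import make_rng_streams


@pytest.fixture
def small_init():
    """A 40x40 landscape with 12 households, cheap to generate."""
    return InitConfig(
        width=40, height=40, n_households=12, road_spacing=10,
        agri_fraction_target=0.4, household_area_mean=30.0,
        household_area_sd=10.0,
    )


@pytest.fixture
def small_config(small_init):
    cfg = ScenarioConfig.from_scenario("C0", seed=7, n_replicates=2)
    cfg.years = 10
    cfg.init = small_init
    return cfg


@pytest.fixture
def small_world(small_init):
    rng = make_rng_streams(11)
    ls, hhs = generate_landscape(
        small_init, rng["landscape"], rng["wealth"], rng["inefficiency"]
    )
    return ls, hhs


@pytest.fixture(scope="session")
def default_generations():
    """Twenty seeded full-size landscape generations for distribution checks."""
    out = []
    cfg = InitConfig()
    for seed in range(20):
        rng = make_rng_streams(seed)
        out.append(
            generate_landscape(
                cfg, rng["landscape"], rng["wealth"], rng["inefficiency"]
            )
        )
    return out


@pytest.fixture
def bare_landscape():
    return Landscape(width=12, height=12)
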