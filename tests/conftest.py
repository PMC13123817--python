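import pytest

from maletfr import ScenarioConfig, Shock, generate_scenario


@pytest.fixture(scope="session")
def constant_scenario():
    """Time-constant rates: SRB 105, TFR 2.1, default mortality, 31 years."""
    return generate_scenario(ScenarioConfig(start_year=2000, end_year=2030))


@pytest.fixture(scope="session")
def symmetric_scenario():
    """SRB 100 and identical male/female hazards: fully sex-symmetric."""
    cfg = ScenarioConfig(
        start_year=2000,
        end_year=2020,
        srb=100.0,
        mortality=__import__("maletfr").MortalityParams(sex_gap=1.0),
    )
    return generate_scenario(cfg)


@pytest.fixture(scope="session")
def shock_scenario():
    """Male hazard tripled in 2010-2012 at ages 18-40 (conflict episode)."""
    cfg = ScenarioConfig(
        start_year=2000,
        end_year=2030,
        shocks=(Shock(2010, 2012, "male", 18, 40, 3.0),),
    )
    return generate_scenario(cfg)
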