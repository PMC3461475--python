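import pytest

from cmrcost import (
    PathwayProbabilities,
    Scenario,
    UnitCostTable,
    calibrated_probabilities,
    load_all_countries,
    load_country,
    printed_probabilities,
)

SPLIT = {"SECHO": 0.85, "CT": 0.13, "SPECT": 0.02}


@pytest.fixture(scope="session")
def german_table() -> UnitCostTable:
    return load_country("germany")


@pytest.fixture(scope="session")
def us_table() -> UnitCostTable:
    return load_country("united_states")


@pytest.fixture(scope="session")
def all_tables() -> dict[str, UnitCostTable]:
    return load_all_countries()


@pytest.fixture(scope="session")
def printed_probs() -> PathwayProbabilities:
    return printed_probabilities()


@pytest.fixture(scope="session")
def calibrated_probs() -> PathwayProbabilities:
    return calibrated_probabilities()


@pytest.fixture
def de_outpatient() -> Scenario:
    return Scenario(country="germany", cmr_setting="outpatient", cxa_setting="outpatient",
                    scenario_id="germany/outpatient_all")


@pytest.fixture
def us_outpatient() -> Scenario:
    return Scenario(country="united_states", cmr_setting="outpatient",
                    cxa_setting="outpatient", scenario_id="united_states/outpatient_all")


def make_table(costs: dict[tuple[str, str], float], country: str = "testland",
               currency: str = "XTS") -> UnitCostTable:
    return UnitCostTable(country=country, currency=currency, costs=costs)


def make_probs(p_pos: float, p_unc: float, split: dict[str, float] | None = None
               ) -> PathwayProbabilities:
    return PathwayProbabilities(
        p_positive=p_pos,
        p_uncertain=p_unc,
        p_negative=1.0 - p_pos - p_unc,
        uncertain_split=dict(split or SPLIT),
    )
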