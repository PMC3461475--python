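"""Two-strategy decision tree and expected per-patient cost compilation.

The model compares, from a health-care payer perspective, two diagnostic
strategies for patients with suspected coronary artery disease:

* **CMR-gatekeeper strategy** — every patient has a stress CMR. Patients
  positive for ischemia and/or infarct scar (fraction ``p_positive``) go on
  to invasive coronary angiography (CXA); patients with an uncertain result
  (``p_uncertain``) have one second-line test (stress echocardiography,
  cardiac CT or SPECT, with fixed split); negative patients
  (``p_negative``) have no further test.
* **CXA-for-all strategy** — every patient has a single CXA.

The expected per-patient cost of the gatekeeper strategy is therefore

    E[cost] = c_CMR + p_positive * c_CXA + p_uncertain * m,

with ``m`` the split-weighted mean second-line cost. The uncertain branch is
terminal: no downstream cost is added after the second-line test. The
comparator strategy costs exactly ``c_CXA`` per patient.

All amounts are in the currency of the scenario's unit-cost table and kept at
full precision; rounding to integer currency units and integer percents is
done only by the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import pandas as pd

from .cost_tables import SECOND_LINE_TESTS, PathwayProbabilities, UnitCostTable
from .errors import ConfigError, UndefinedPercentageError


@dataclass(frozen=True)
class Scenario:
    """Care settings chosen for each test in one country.

    ``cxa_setting`` applies both to the confirmatory CXA after a positive CMR
    and to the hypothetical CXA-for-all comparator. Second-line tests are
    outpatient procedures in every study scenario, but the setting is
    configurable.
    """

    country: str
    cmr_setting: str
    cxa_setting: str
    secondline_setting: str = "outpatient"
    scenario_id: str = ""
    label: str = ""

    def validate_against(self, table: UnitCostTable) -> None:
        """Raise MissingCostError unless every referenced pair is priced."""
        table.unit_cost("CMR", self.cmr_setting)
        table.unit_cost("CXA", self.cxa_setting)
        for test in SECOND_LINE_TESTS:
            table.unit_cost(test, self.secondline_setting)


@dataclass(frozen=True)
class StrategyComparison:
    """Expected per-patient costs of both strategies for one scenario."""

    scenario: Scenario
    currency: str
    cost_cmr_strategy: float
    cost_cxa_strategy: float

    @property
    def absolute_difference(self) -> float:
        """CXA-for-all cost minus gatekeeper cost (positive = CMR cheaper)."""
        return self.cost_cxa_strategy - self.cost_cmr_strategy

    @property
    def percent_saving(self) -> float:
        return percent_saving(self.cost_cmr_strategy, self.cost_cxa_strategy)


def uncertain_followup_cost(
    table: UnitCostTable, probs: PathwayProbabilities, scenario: Scenario
) -> float:
    """Split-weighted mean cost of the second-line test in the uncertain branch.

    Returns sum over second-line tests of split(t) * unit_cost(t, setting).
    The branch is terminal — nothing is added after the second-line test.
    """
    return sum(
        frac * table.unit_cost(test, scenario.secondline_setting)
        for test, frac in probs.uncertain_split.items()
    )


def expected_cost_cmr_strategy(
    table: UnitCostTable,
    probs: PathwayProbabilities,
    scenario: Scenario,
    *,
    cmr_price: float | None = None,
) -> float:
    """Expected per-patient cost of the CMR-gatekeeper strategy.

    Parameters
    ----------
    cmr_price
        Optional override of the CMR unit cost (used by the breakeven
        solver); defaults to the table's price in ``scenario.cmr_setting``.
    """
    c_cmr = table.unit_cost("CMR", scenario.cmr_setting) if cmr_price is None else float(cmr_price)
    c_cxa = table.unit_cost("CXA", scenario.cxa_setting)
    m = uncertain_followup_cost(table, probs, scenario)
    return c_cmr + probs.p_positive * c_cxa + probs.p_uncertain * m


def expected_cost_cxa_strategy(table: UnitCostTable, scenario: Scenario) -> float:
    """Expected per-patient cost of the CXA-for-all comparator: one CXA each."""
    return table.unit_cost("CXA", scenario.cxa_setting)


def percent_saving(cost_cmr_strategy: float, cost_cxa_strategy: float) -> float:
    """Percent cost saving of the gatekeeper strategy relative to CXA-for-all.

    ``100 * (cxa - cmr) / cxa``; positive when the CMR strategy is cheaper,
    negative when it costs more (the US outpatient case).

    Raises
    ------
    UndefinedPercentageError
        If the comparator cost is zero.
    """
    if cost_cxa_strategy == 0:
        raise UndefinedPercentageError("comparator (CXA-for-all) cost is zero")
    return 100.0 * (cost_cxa_strategy - cost_cmr_strategy) / cost_cxa_strategy


def compare_strategies(
    table: UnitCostTable, probs: PathwayProbabilities, scenario: Scenario
) -> StrategyComparison:
    """Both expected costs for one scenario, as a StrategyComparison."""
    return StrategyComparison(
        scenario=scenario,
        currency=table.currency,
        cost_cmr_strategy=expected_cost_cmr_strategy(table, probs, scenario),
        cost_cxa_strategy=expected_cost_cxa_strategy(table, scenario),
    )


#: Stable column order of the results matrix.
MATRIX_COLUMNS = (
    "scenario_id",
    "country",
    "currency",
    "cmr_setting",
    "cxa_setting",
    "cost_cmr_strategy",
    "cost_cxa_strategy",
    "absolute_difference",
    "percent_saving",
)


def compile_results_matrix(
    tables: Mapping[str, UnitCostTable],
    probs: PathwayProbabilities,
    scenarios: Iterable[Scenario],
) -> pd.DataFrame:
    """One row per scenario with both strategy costs, difference and saving.

    ``tables`` is keyed by the scenario ``country`` field. Row order follows
    the input order. Missing-cost errors carry the scenario id.
    """
    rows = []
    for scenario in scenarios:
        try:
            table = tables[scenario.country]
        except KeyError:
            raise ConfigError(
                f"no unit-cost table for country {scenario.country!r}"
                f" (scenario {scenario.scenario_id or scenario.label!r})"
            ) from None
        try:
            comparison = compare_strategies(table, probs, scenario)
        except Exception as exc:
            exc.add_note(f"while compiling scenario {scenario.scenario_id or scenario.label!r}")
            raise
        rows.append(
            {
                "scenario_id": scenario.scenario_id,
                "country": scenario.country,
                "currency": comparison.currency,
                "cmr_setting": scenario.cmr_setting,
                "cxa_setting": scenario.cxa_setting,
                "cost_cmr_strategy": comparison.cost_cmr_strategy,
                "cost_cxa_strategy": comparison.cost_cxa_strategy,
                "absolute_difference": comparison.absolute_difference,
                "percent_saving": comparison.percent_saving,
            }
        )
    return pd.DataFrame(rows, columns=list(MATRIX_COLUMNS))


def study_scenarios() -> list[Scenario]:
    """The ten published scenario rows, in table order.

    Germany contributes four rows (outpatient CMR and pre-inpatient CMR,
    each against outpatient and inpatient CXA); the United Kingdom,
    Switzerland and the United States contribute outpatient-CXA and
    inpatient-CXA rows with outpatient CMR.
    """
    scenarios: list[Scenario] = []

    def add(country: str, sid: str, cmr: str, cxa: str, label: str) -> None:
        scenarios.append(
            Scenario(
                country=country,
                cmr_setting=cmr,
                cxa_setting=cxa,
                scenario_id=f"{country}/{sid}",
                label=label,
            )
        )

    add("germany", "outpatient_all", "outpatient", "outpatient",
        "All tests performed as outpatient procedures in Germany")
    add("germany", "inpatient_cxa", "outpatient", "inpatient",
        "CXA as an inpatient test in Germany")
    add("germany", "preinpatient_cmr_outpatient_cxa", "pre_inpatient", "outpatient",
        "CMR as pre-inpatient test and CXA outpatient test in Germany")
    add("germany", "preinpatient_cmr_inpatient_cxa", "pre_inpatient", "inpatient",
        "CMR as pre-inpatient test and CXA as an inpatient test in Germany")
    add("united_kingdom", "outpatient_all", "outpatient", "outpatient",
        "All tests performed as outpatient procedures in the United Kingdom")
    add("united_kingdom", "inpatient_cxa", "outpatient", "inpatient",
        "CXA performed as an inpatient procedure in the United Kingdom")
    add("switzerland", "outpatient_all", "outpatient", "outpatient",
        "All tests performed as outpatient procedures in Switzerland")
    add("switzerland", "inpatient_cxa", "outpatient", "inpatient",
        "CXA performed as an inpatient procedure in Switzerland")
    add("united_states", "outpatient_all", "outpatient", "outpatient",
        "All tests performed as outpatient procedures in the United States")
    add("united_states", "inpatient_cxa", "outpatient", "inpatient",
        "CXA performed as an inpatient procedure in the United States")
    return scenarios


def scenario_by_id(scenario_id: str) -> Scenario:
    """Look one of the study scenarios up by id (e.g. ``germany/outpatient_all``)."""
    for scenario in study_scenarios():
        if scenario.scenario_id == scenario_id:
            return scenario
    raise ConfigError(f"unknown scenario id {scenario_id!r}")


def with_secondline_setting(scenario: Scenario, setting: str) -> Scenario:
    """Copy of a scenario with a different second-line care setting."""
    return replace(scenario, secondline_setting=setting)
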