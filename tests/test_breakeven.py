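"""Breakeven CMR price (closed form vs root finder) and prevalence threshold."""

import numpy as np
import pytest

from cmrcost import (
    Scenario,
    breakeven_by_bisection,
    breakeven_cmr_price,
    percent_saving,
    prevalence_threshold,
    scenario_by_id,
    solve_cost_neutral_price,
    study_scenarios,
)
from cmrcost.breakeven import cost_difference_at_cmr_price
from cmrcost.errors import BracketingError
from conftest import make_probs, make_table

# published cost-neutral reimbursement levels, keyed by scenario id
PUBLISHED_BREAKEVENS = {
    "germany/outpatient_all": 460,
    "united_kingdom/outpatient_all": 825,
    "switzerland/outpatient_all": 2015,
    "united_states/inpatient_cxa": 2085,
}


@pytest.mark.parametrize("sid,published", sorted(PUBLISHED_BREAKEVENS.items()))
def test_breakeven_reproduces_published_values(sid, published, all_tables,
                                               calibrated_probs):
    scenario = scenario_by_id(sid)
    result = breakeven_cmr_price(all_tables[scenario.country], calibrated_probs, scenario)
    assert result.breakeven_cmr_price == pytest.approx(published, rel=0.005)


def test_headroom_is_breakeven_minus_current_tariff(all_tables, calibrated_probs):
    scenario = scenario_by_id("germany/outpatient_all")
    result = breakeven_cmr_price(all_tables["germany"], calibrated_probs, scenario)
    assert result.current_cmr_price == 164
    assert result.headroom == pytest.approx(result.breakeven_cmr_price - 164)


def test_breakeven_equals_comparator_when_gatekeeper_never_escalates(german_table,
                                                                     de_outpatient):
    probs = make_probs(0.0, 0.0)
    result = breakeven_cmr_price(german_table, probs, de_outpatient)
    assert result.breakeven_cmr_price == 588


def test_plugging_breakeven_back_equalizes_strategies(all_tables, calibrated_probs):
    for scenario in study_scenarios():
        table = all_tables[scenario.country]
        price = breakeven_cmr_price(table, calibrated_probs, scenario).breakeven_cmr_price
        diff = cost_difference_at_cmr_price(table, calibrated_probs, scenario, price)
        assert abs(diff) < 1e-6


def test_bisection_agrees_with_closed_form_on_bundled_scenarios(all_tables,
                                                                calibrated_probs):
    for sid, hi in [("germany/outpatient_all", 588),
                    ("united_states/inpatient_cxa", 2652)]:
        scenario = scenario_by_id(sid)
        table = all_tables[scenario.country]
        closed = breakeven_cmr_price(table, calibrated_probs, scenario).breakeven_cmr_price
        numeric = breakeven_by_bisection(table, calibrated_probs, scenario, 0, hi)
        assert numeric == pytest.approx(closed, abs=1e-6)


def test_bisection_agrees_with_closed_form_on_random_tables():
    """Closed form == root finder on 100 randomized cost tables."""
    rng = np.random.default_rng(42)
    scenario = Scenario("testland", "outpatient", "outpatient")
    for _ in range(100):
        costs = {(test, "outpatient"): float(rng.uniform(1, 5000))
                 for test in ("CXA", "CMR", "SECHO", "CT", "SPECT")}
        table = make_table(costs)
        p = rng.dirichlet([2, 1, 4])
        probs = make_probs(float(p[0]), float(p[1]))
        closed = breakeven_cmr_price(table, probs, scenario).breakeven_cmr_price
        numeric = breakeven_by_bisection(table, probs, scenario, -10_000, 10_000)
        assert numeric == pytest.approx(closed, abs=1e-6)


def test_no_sign_change_raises_bracketing_error(german_table, calibrated_probs,
                                                de_outpatient):
    with pytest.raises(BracketingError):
        breakeven_by_bisection(german_table, calibrated_probs, de_outpatient, 0, 0)


def test_breakeven_decreases_with_positive_fraction(german_table, de_outpatient):
    prices = [
        breakeven_cmr_price(german_table, make_probs(p, 0.06),
                            de_outpatient).breakeven_cmr_price
        for p in np.linspace(0.0, 0.9, 10)
    ]
    assert all(b < a for a, b in zip(prices, prices[1:]))


def test_generic_solver_matches_cmr_case(german_table, calibrated_probs, de_outpatient):
    closed = breakeven_cmr_price(german_table, calibrated_probs,
                                 de_outpatient).breakeven_cmr_price
    generic = solve_cost_neutral_price(german_table, calibrated_probs, de_outpatient,
                                       "CMR", "outpatient", 0, 588)
    assert generic == pytest.approx(closed, abs=1e-6)


def test_prevalence_threshold_germany_and_us(all_tables, calibrated_probs):
    """p* ~ 0.710 in German outpatient care, ~ 0.131 in the US, where the
    registry's ~0.21 positive rate already exceeds it (CMR costs more)."""
    de = prevalence_threshold(all_tables["germany"], calibrated_probs,
                              scenario_by_id("germany/outpatient_all"))
    us = prevalence_threshold(all_tables["united_states"], calibrated_probs,
                              scenario_by_id("united_states/outpatient_all"))
    assert de == pytest.approx(0.710, abs=0.002)
    assert us == pytest.approx(0.131, abs=0.002)
    assert calibrated_probs.p_positive < de
    assert calibrated_probs.p_positive > us


def test_free_gatekeeper_always_saves():
    table = make_table({("CXA", "outpatient"): 500, ("CMR", "outpatient"): 0,
                        ("SECHO", "outpatient"): 90, ("CT", "outpatient"): 90,
                        ("SPECT", "outpatient"): 90})
    probs = make_probs(0.2, 0.0)
    scenario = Scenario("testland", "outpatient", "outpatient")
    assert prevalence_threshold(table, probs, scenario) == 1.0


def test_threshold_clamped_to_unit_interval():
    table = make_table({("CXA", "outpatient"): 100, ("CMR", "outpatient"): 5000,
                        ("SECHO", "outpatient"): 1, ("CT", "outpatient"): 1,
                        ("SPECT", "outpatient"): 1})
    probs = make_probs(0.2, 0.1)
    scenario = Scenario("testland", "outpatient", "outpatient")
    assert prevalence_threshold(table, probs, scenario) == 0.0


def test_sign_coherence_saving_headroom_and_threshold(all_tables, calibrated_probs):
    """percent_saving > 0 <=> current price < breakeven <=> p_positive < p*."""
    for scenario in study_scenarios():
        table = all_tables[scenario.country]
        result = breakeven_cmr_price(table, calibrated_probs, scenario)
        saving = percent_saving(
            result.current_cmr_price
            + calibrated_probs.p_positive * table.unit_cost("CXA", scenario.cxa_setting)
            + calibrated_probs.p_uncertain
            * sum(f * table.unit_cost(t, scenario.secondline_setting)
                  for t, f in calibrated_probs.uncertain_split.items()),
            table.unit_cost("CXA", scenario.cxa_setting),
        )
        p_star = prevalence_threshold(table, calibrated_probs, scenario)
        assert (saving > 0) == (result.headroom > 0)
        assert (saving > 0) == (calibrated_probs.p_positive < p_star)
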