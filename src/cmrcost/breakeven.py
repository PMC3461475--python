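"""Breakeven CMR price and cost-neutral prevalence threshold.

Because the gatekeeper expectation is affine in the CMR unit price,

    E[cost_CMR-strategy](c) = c + p_positive * c_CXA + p_uncertain * m,

the price at which both strategies cost the same has the closed form

    c* = c_CXA - p_positive * c_CXA - p_uncertain * m.

The closed form is cross-checked by a numerical root finder
(:func:`breakeven_by_bisection`) that knows nothing about affinity.

The same algebra, solved for ``p_positive`` at a fixed CMR price, gives the
prevalence threshold p* = (c_CXA - c_CMR - p_uncertain * m) / c_CXA: the
positive-CMR fraction above which the gatekeeper strategy stops being
cost-saving. The uncertain fraction and its split are held fixed while
``p_positive`` varies (the negative fraction absorbs the change); no joint
model of the positive and uncertain fractions is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .cost_tables import PathwayProbabilities, UnitCostTable
from .errors import BracketingError
from .model import (
    Scenario,
    expected_cost_cmr_strategy,
    expected_cost_cxa_strategy,
    uncertain_followup_cost,
)

#: Absolute tolerance (currency units) of the numerical breakeven solver.
ROOT_TOL = 1e-6


@dataclass(frozen=True)
class BreakevenResult:
    """Breakeven CMR reimbursement for one scenario.

    ``headroom`` is breakeven minus current price: positive headroom means
    the tariff could rise by that much before the strategies cost the same.
    The breakeven may exceed any realistic tariff; it is returned unclamped.
    """

    scenario: Scenario
    currency: str
    breakeven_cmr_price: float
    current_cmr_price: float

    @property
    def headroom(self) -> float:
        return self.breakeven_cmr_price - self.current_cmr_price


def breakeven_cmr_price(
    table: UnitCostTable, probs: PathwayProbabilities, scenario: Scenario
) -> BreakevenResult:
    """Closed-form CMR price at which the two strategies' costs are equal."""
    c_cxa = table.unit_cost("CXA", scenario.cxa_setting)
    m = uncertain_followup_cost(table, probs, scenario)
    price = c_cxa - probs.p_positive * c_cxa - probs.p_uncertain * m
    return BreakevenResult(
        scenario=scenario,
        currency=table.currency,
        breakeven_cmr_price=price,
        current_cmr_price=table.unit_cost("CMR", scenario.cmr_setting),
    )


def cost_difference_at_cmr_price(
    table: UnitCostTable, probs: PathwayProbabilities, scenario: Scenario, cmr_price: float
) -> float:
    """Gatekeeper cost minus comparator cost when CMR is reimbursed at ``cmr_price``."""
    return expected_cost_cmr_strategy(
        table, probs, scenario, cmr_price=cmr_price
    ) - expected_cost_cxa_strategy(table, scenario)


def breakeven_by_bisection(
    table: UnitCostTable,
    probs: PathwayProbabilities,
    scenario: Scenario,
    lo: float,
    hi: float,
) -> float:
    """Numerical breakeven CMR price: root of the cost difference on [lo, hi].

    Serves as an independent check on :func:`breakeven_cmr_price`; agrees
    with the closed form to ``ROOT_TOL``.

    Raises
    ------
    BracketingError
        If the cost difference does not change sign on the bracket.
    """
    f_lo = cost_difference_at_cmr_price(table, probs, scenario, lo)
    f_hi = cost_difference_at_cmr_price(table, probs, scenario, hi)
    if f_lo == 0.0:
        return float(lo)
    if f_hi == 0.0:
        return float(hi)
    if f_lo * f_hi > 0:
        raise BracketingError(
            f"cost difference does not change sign on [{lo}, {hi}]"
            f" (f(lo)={f_lo:.6g}, f(hi)={f_hi:.6g})"
        )
    return float(
        brentq(
            lambda c: cost_difference_at_cmr_price(table, probs, scenario, c),
            lo,
            hi,
            xtol=ROOT_TOL,
        )
    )


def solve_cost_neutral_price(
    table: UnitCostTable,
    probs: PathwayProbabilities,
    scenario: Scenario,
    test: str,
    setting: str,
    lo: float,
    hi: float,
) -> float:
    """Generic solver: price of any (test, setting) making the strategies cost-equal.

    Only the CMR-price case has a published anchor; other parameters are
    exposed for exploration. Solved numerically on the bracket [lo, hi].
    """
    def diff(price: float) -> float:
        patched = table.with_cost(test, setting, price)
        return expected_cost_cmr_strategy(patched, probs, scenario) - expected_cost_cxa_strategy(
            patched, scenario
        )

    f_lo, f_hi = diff(lo), diff(hi)
    if f_lo == 0.0:
        return float(lo)
    if f_hi == 0.0:
        return float(hi)
    if f_lo * f_hi > 0:
        raise BracketingError(
            f"cost difference does not change sign on [{lo}, {hi}] for ({test}, {setting})"
        )
    return float(brentq(diff, lo, hi, xtol=ROOT_TOL))


def prevalence_threshold(
    table: UnitCostTable, probs: PathwayProbabilities, scenario: Scenario
) -> float:
    """Positive-CMR fraction above which the gatekeeper strategy stops saving.

    Holding the uncertain fraction and its split fixed, returns

        p* = (c_CXA - c_CMR - p_uncertain * m) / c_CXA,

    clamped to [0, 1]. The CMR strategy is cost-saving iff
    ``p_positive < p*``. As disease prevalence in the referred population
    rises, more gatekeeper patients need the confirmatory angiography and
    the saving erodes; p* marks where it vanishes.
    """
    c_cxa = table.unit_cost("CXA", scenario.cxa_setting)
    c_cmr = table.unit_cost("CMR", scenario.cmr_setting)
    m = uncertain_followup_cost(table, probs, scenario)
    p_star = (c_cxa - c_cmr - probs.p_uncertain * m) / c_cxa
    return min(1.0, max(0.0, p_star))
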