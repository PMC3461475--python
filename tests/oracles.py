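"""Independent brute-force oracle for the gatekeeper expectation.

Enumerates every terminal pathway of the decision tree (positive -> CXA;
uncertain -> one of the three second-line tests; negative -> stop) and sums
probability-weighted deterministic costs. Deliberately avoids the analytic
compilation in cmrcost.model so the two routes stay independent.
"""

from cmrcost import PathwayProbabilities, Scenario, UnitCostTable


def enumerate_pathways(
    table: UnitCostTable, probs: PathwayProbabilities, scenario: Scenario
) -> list[tuple[float, float]]:
    """All (probability, cost) terminal pathways of the gatekeeper tree."""
    c_cmr = table.unit_cost("CMR", scenario.cmr_setting)
    pathways = [
        (probs.p_positive, c_cmr + table.unit_cost("CXA", scenario.cxa_setting)),
        (probs.p_negative, c_cmr),
    ]
    for test, frac in probs.uncertain_split.items():
        pathways.append(
            (probs.p_uncertain * frac,
             c_cmr + table.unit_cost(test, scenario.secondline_setting))
        )
    return pathways


def brute_force_expected_cost(
    table: UnitCostTable, probs: PathwayProbabilities, scenario: Scenario
) -> float:
    """Expectation by exhaustive pathway enumeration."""
    return sum(p * cost for p, cost in enumerate_pathways(table, probs, scenario))
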