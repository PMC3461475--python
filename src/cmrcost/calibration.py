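"""Recovery of the registry pathway proportions from published per-patient costs.

The published branch fractions (21% positive, 6% uncertain, 73% negative) are
rounded; compiling the expectation with them misses some published table cells
by a few currency units. Because each published gatekeeper cost is affine in
the unknown fractions,

    cost_i = c_CMR,i + p_positive * c_CXA,i + p_uncertain * m_i,

two (or more) published rows form a linear system in
(p_positive, p_uncertain) that can be inverted. Calibrating on the two German
pre-inpatient rows — same CMR price (393), different CXA setting, hence the
best-conditioned 2x2 system — recovers fractions that reproduce the
remaining published costs out of sample to within ~0.5%.

With more than two rows the system is solved by ordinary least squares and
per-row residuals expose the publication's own rounding noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

from .cost_tables import (
    PathwayProbabilities,
    UnitCostTable,
    bundled_data_path,
    load_country,
    printed_probabilities,
)
from .errors import CalibrationError, DegenerateSystemError, ValidationError
from .model import Scenario, scenario_by_id

#: Relative condition-number floor below which the system is declared degenerate.
_RANK_TOL = 1e-9


@dataclass(frozen=True)
class CalibrationInput:
    """Rows of a published cost table used to infer pathway proportions.

    ``rows`` pairs each scenario with its published CMR-strategy cost; all
    rows must price against the same ``table``. ``uncertain_split`` is the
    known second-line split (it multiplies the uncertain fraction and cannot
    be identified separately from it).
    """

    rows: Sequence[tuple[Scenario, float]]
    table: UnitCostTable
    uncertain_split: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise CalibrationError("calibration needs at least two rows")


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated proportions plus the least-squares diagnostics."""

    probabilities: PathwayProbabilities
    residuals: np.ndarray  # published minus fitted cost, one per row
    scenario_ids: tuple[str, ...]

    def implied_counts(self, n: int) -> dict[str, float]:
        """Implied patient counts at registry size ``n`` (not rounded)."""
        p = self.probabilities
        return {
            "positive": n * p.p_positive,
            "uncertain": n * p.p_uncertain,
            "negative": n * p.p_negative,
        }


def calibrate(input: CalibrationInput) -> CalibrationResult:
    """Solve the linear system in (p_positive, p_uncertain) from published rows.

    Exact for two rows, ordinary least squares for more. The negative
    fraction is the complement. Raises
    :class:`~cmrcost.errors.DegenerateSystemError` when the rows are
    collinear (e.g. two rows with the same CXA setting) and
    :class:`~cmrcost.errors.CalibrationError` when the solution leaves
    [0, 1].
    """
    table = input.table
    split = input.uncertain_split
    design = np.empty((len(input.rows), 2))
    rhs = np.empty(len(input.rows))
    for i, (scenario, printed_cost) in enumerate(input.rows):
        m = sum(
            frac * table.unit_cost(test, scenario.secondline_setting)
            for test, frac in split.items()
        )
        design[i, 0] = table.unit_cost("CXA", scenario.cxa_setting)
        design[i, 1] = m
        rhs[i] = printed_cost - table.unit_cost("CMR", scenario.cmr_setting)

    if np.linalg.matrix_rank(design, tol=_RANK_TOL * np.abs(design).max()) < 2:
        raise DegenerateSystemError(
            "calibration rows are collinear; use rows differing in CXA setting"
        )
    solution, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    p_positive, p_uncertain = (float(x) for x in solution)
    p_negative = 1.0 - p_positive - p_uncertain
    try:
        probs = PathwayProbabilities(
            p_positive=p_positive,
            p_uncertain=p_uncertain,
            p_negative=p_negative,
            uncertain_split=dict(split),
        )
    except ValidationError as exc:
        raise CalibrationError(f"calibrated proportions are not valid fractions: {exc}") from exc
    return CalibrationResult(
        probabilities=probs,
        residuals=rhs - design @ solution,
        scenario_ids=tuple(s.scenario_id for s, _ in input.rows),
    )


def calibrate_proportions(input: CalibrationInput) -> PathwayProbabilities:
    """Calibrated :class:`PathwayProbabilities` (see :func:`calibrate`)."""
    return calibrate(input).probabilities


# ---------------------------------------------------------------------------
# bundled reference results

def load_reference_results() -> dict:
    """Published per-scenario costs, percent savings and breakevens."""
    with open(bundled_data_path("reference_results.yaml"), encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def default_calibration_input() -> CalibrationInput:
    """The default calibration system: the two German pre-inpatient rows."""
    reference = load_reference_results()
    table = load_country("germany")
    split = dict(printed_probabilities().uncertain_split)
    rows = [
        (scenario_by_id(sid), float(reference["printed_costs"][sid][0]))
        for sid in reference["calibration_rows"]
    ]
    return CalibrationInput(rows=rows, table=table, uncertain_split=split)


def calibrated_probabilities() -> PathwayProbabilities:
    """Pathway proportions recovered from the bundled German pre-inpatient rows.

    These are the package's default proportions; the printed rounded preset
    is available via :func:`cmrcost.cost_tables.printed_probabilities`.
    """
    return calibrate_proportions(default_calibration_input())
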