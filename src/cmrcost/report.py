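"""Reporting layer: rounding, formatting and reproduction checks.

The model keeps full precision everywhere; this module owns the only
rounding in the package. Money is rounded half-up to integer currency units
and percents half-up to integers, matching how the reference tables print
them. Thousands separators are applied at display time only.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .model import MATRIX_COLUMNS


def round_half_up(value: float, digits: int = 0) -> float:
    """Decimal half-up rounding (2.5 -> 3, -2.5 -> -3), unlike banker's rounding."""
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def format_money(value: float, currency: str = "") -> str:
    """Integer half-up rounding with thousands separators, e.g. ``1,207 EUR``."""
    amount = f"{int(round_half_up(value)):,}"
    return f"{amount} {currency}".strip()


def rounded_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Copy of a results matrix with money and percent columns rounded half-up."""
    out = matrix.copy()
    for col in ("cost_cmr_strategy", "cost_cxa_strategy", "absolute_difference",
                "percent_saving"):
        out[col] = out[col].map(lambda v: int(round_half_up(v)))
    return out


def write_matrix(matrix: pd.DataFrame, csv_path=None, json_path=None) -> None:
    """Write a results matrix with the documented stable column order."""
    matrix = matrix[list(MATRIX_COLUMNS)]
    if csv_path is not None:
        matrix.to_csv(csv_path, index=False)
    if json_path is not None:
        matrix.to_json(json_path, orient="records", indent=2)


@dataclass(frozen=True)
class CheckFailure:
    quantity: str
    scenario_id: str
    expected: float
    actual: float
    tolerance: str

    def __str__(self) -> str:
        return (
            f"{self.quantity} for {self.scenario_id}: expected {self.expected},"
            f" got {self.actual:.4f} (tolerance {self.tolerance})"
        )


def check_costs(matrix: pd.DataFrame, printed_costs: dict, rel_tol: float = 0.005
                ) -> list[CheckFailure]:
    """Compare compiled strategy costs against reference values, relative tolerance."""
    failures = []
    indexed = matrix.set_index("scenario_id")
    for sid, (ref_cmr, ref_cxa) in printed_costs.items():
        row = indexed.loc[sid]
        for quantity, expected, actual in (
            ("cost_cmr_strategy", ref_cmr, row["cost_cmr_strategy"]),
            ("cost_cxa_strategy", ref_cxa, row["cost_cxa_strategy"]),
        ):
            if abs(actual - expected) > rel_tol * abs(expected):
                failures.append(CheckFailure(quantity, sid, expected, actual,
                                             f"{100 * rel_tol:g}% relative"))
    return failures


def check_percent_savings(matrix: pd.DataFrame, printed_savings: dict,
                          point_tol: float = 1.0) -> list[CheckFailure]:
    """Compare half-up rounded percent savings against reference, in points."""
    failures = []
    indexed = matrix.set_index("scenario_id")
    for sid, expected in printed_savings.items():
        actual = round_half_up(float(indexed.loc[sid, "percent_saving"]))
        if abs(actual - expected) > point_tol:
            failures.append(CheckFailure("percent_saving", sid, expected, actual,
                                         f"{point_tol:g} percentage points"))
    return failures


def check_breakevens(breakevens: dict, printed_breakeven: dict,
                     rel_tol: float = 0.005) -> list[CheckFailure]:
    """Compare computed breakeven prices (by scenario id) against reference."""
    failures = []
    for sid, expected in printed_breakeven.items():
        actual = breakevens[sid]
        if abs(actual - expected) > rel_tol * abs(expected):
            failures.append(CheckFailure("breakeven_cmr_price", sid, expected, actual,
                                         f"{100 * rel_tol:g}% relative"))
    return failures
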