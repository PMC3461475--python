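"""End-to-end reproduction of the published cost analysis.

Glue layer behind the ``reproduce-paper`` CLI subcommand: calibrates the
pathway proportions, compiles the ten-scenario results matrix, computes the
four anchored breakeven prices, and optionally checks everything against the
bundled reference values. All numbers in the bundle are full precision;
rounded values in the written reports are derived from them at write time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from .breakeven import breakeven_cmr_price
from .calibration import (
    CalibrationInput,
    CalibrationResult,
    calibrate,
    load_reference_results,
)
from .cost_tables import UnitCostTable, load_cost_table, printed_probabilities
from .errors import ConfigError
from .model import (
    PathwayProbabilities,
    compile_results_matrix,
    scenario_by_id,
    study_scenarios,
)
from .report import (
    CheckFailure,
    check_breakevens,
    check_costs,
    check_percent_savings,
    round_half_up,
    rounded_matrix,
    write_matrix,
)

COUNTRY_FILES = (
    "germany.yaml",
    "united_kingdom.yaml",
    "switzerland.yaml",
    "united_states.yaml",
)


@dataclass
class ReportBundle:
    """Everything one reproduction run produced, at full precision."""

    results_matrix: pd.DataFrame
    percent_savings: dict[str, float]
    breakevens: dict[str, float]
    calibration: CalibrationResult
    probabilities: PathwayProbabilities
    metadata: dict
    failures: list[CheckFailure] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failures


def load_config_dir(config_dir: str | Path) -> dict[str, UnitCostTable]:
    """Load the four country tables from a config directory, keyed by country key."""
    config_dir = Path(config_dir)
    if not config_dir.is_dir():
        raise ConfigError(f"config directory not found: {config_dir}")
    tables: dict[str, UnitCostTable] = {}
    for fname in COUNTRY_FILES:
        path = config_dir / fname
        if not path.exists():
            raise ConfigError(f"missing country fixture {fname!r} in {config_dir}")
        tables[path.stem] = load_cost_table(path)
    return tables


def _config_hash(config_dir: Path) -> str:
    digest = hashlib.sha256()
    for path in sorted(config_dir.glob("*.yaml")):
        digest.update(path.name.encode())
        digest.update(path.read_bytes())
    return digest.hexdigest()[:16]


def run_paper_reproduction(
    config_dir: str | Path,
    out_dir: str | Path | None = None,
    *,
    check: bool = False,
    seed: int = 0,
) -> ReportBundle:
    """Reproduce the published tables: calibrate, compile, break even, report.

    Writes (when ``out_dir`` is given) the full-precision and rounded
    results matrices, the savings/breakeven tables and the calibration
    report. With ``check=True`` the bundle's ``failures`` list is populated
    by comparing against the bundled reference values; callers (the CLI)
    turn a non-empty list into a non-zero exit.
    """
    config_dir = Path(config_dir)
    tables = load_config_dir(config_dir)
    reference = load_reference_results()
    split = dict(printed_probabilities().uncertain_split)

    rows = [
        (scenario_by_id(sid), float(reference["printed_costs"][sid][0]))
        for sid in reference["calibration_rows"]
    ]
    calibration = calibrate(
        CalibrationInput(rows=rows, table=tables["germany"], uncertain_split=split)
    )
    probs = calibration.probabilities

    scenarios = study_scenarios()
    matrix = compile_results_matrix(tables, probs, scenarios)
    savings = dict(zip(matrix["scenario_id"], matrix["percent_saving"]))

    breakevens = {
        sid: breakeven_cmr_price(tables[scenario_by_id(sid).country], probs,
                                 scenario_by_id(sid)).breakeven_cmr_price
        for sid in reference["printed_breakeven"]
    }

    try:
        pkg_version = version("cmrcost")
    except PackageNotFoundError:  # running from a source tree
        pkg_version = "unknown"
    metadata = {
        "config_hash": _config_hash(config_dir),
        "seed": int(seed),
        "version": pkg_version,
        "calibration_rows": list(reference["calibration_rows"]),
    }

    failures: list[CheckFailure] = []
    if check:
        failures += check_costs(matrix, reference["printed_costs"])
        failures += check_percent_savings(matrix, reference["printed_percent_savings"])
        failures += check_breakevens(breakevens, reference["printed_breakeven"])

    bundle = ReportBundle(
        results_matrix=matrix,
        percent_savings=savings,
        breakevens=breakevens,
        calibration=calibration,
        probabilities=probs,
        metadata=metadata,
        failures=failures,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: ReportBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_matrix(bundle.results_matrix, csv_path=out_dir / "results_matrix.csv",
                 json_path=out_dir / "results_matrix.json")
    rounded_matrix(bundle.results_matrix).to_csv(out_dir / "results_matrix_rounded.csv",
                                                 index=False)
    p = bundle.probabilities
    report = {
        "metadata": bundle.metadata,
        "percent_savings_rounded": {
            sid: int(round_half_up(v)) for sid, v in bundle.percent_savings.items()
        },
        "breakeven_cmr_price": bundle.breakevens,
        "calibration": {
            "p_positive": p.p_positive,
            "p_uncertain": p.p_uncertain,
            "p_negative": p.p_negative,
            "uncertain_split": dict(p.uncertain_split),
            "residuals": [float(r) for r in bundle.calibration.residuals],
            "rows": list(bundle.calibration.scenario_ids),
        },
        "check_failures": [str(f) for f in bundle.failures],
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n",
                                         encoding="utf-8")
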