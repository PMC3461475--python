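"""Unit-cost tables and patient-pathway proportions.

The model's inputs are (i) a per-country table of tariff unit costs, one
amount per (test, care setting) pair, and (ii) the pathway proportions of the
registry cohort: the fractions of patients whose gatekeeper CMR is read as
positive, uncertain or negative, plus the split of second-line tests
(stress echocardiography, cardiac CT, SPECT) among the uncertain group.

Tables are currency-tagged and amounts from different tables are never summed;
all arithmetic in the model stays within one table. Amounts are kept at full
precision; rounding happens only in the reporting layer.

Config format (YAML, one file per country)::

    country: Germany
    currency: EUR
    costs:
      CXA:   {outpatient: 588, inpatient: 1207}
      CMR:   {outpatient: 164, pre_inpatient: 393}
      SECHO: {outpatient: 94}
      CT:    {outpatient: 165}
      SPECT: {outpatient: 275}

and a shared probabilities file::

    p_positive: 0.21
    p_uncertain: 0.06
    p_negative: 0.73
    uncertain_split: {SECHO: 0.85, CT: 0.13, SPECT: 0.02}

A (test, setting) pair absent from the file is *unpriced*, not zero: asking
for it raises :class:`~cmrcost.errors.MissingCostError`. The German
``pre_inpatient`` setting, for example, exists only for CMR (a same-day
admitted CMR reimbursed under a dedicated public-sector code).
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, MissingCostError, ValidationError

TESTS = ("CXA", "CMR", "SECHO", "CT", "SPECT")
SETTINGS = ("outpatient", "inpatient", "pre_inpatient")
SECOND_LINE_TESTS = ("SECHO", "CT", "SPECT")

#: Sum-to-one tolerance for probability vectors.
PROB_TOL = 1e-9

_COUNTRY_FILES = {
    "germany": "germany.yaml",
    "united_kingdom": "united_kingdom.yaml",
    "switzerland": "switzerland.yaml",
    "united_states": "united_states.yaml",
}


@dataclass(frozen=True)
class UnitCostTable:
    """Per-country mapping (test, setting) -> unit cost, tagged with a currency.

    Parameters
    ----------
    country
        Human-readable country label (e.g. ``"Germany"``).
    currency
        ISO-4217-style currency label (``EUR``, ``GBP``, ``CHF``, ``USD``).
    costs
        Mapping from ``(test, setting)`` to a non-negative amount in
        ``currency``. Pairs not present are unpriced.
    """

    country: str
    currency: str
    costs: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (test, setting), amount in self.costs.items():
            if test not in TESTS:
                raise ValidationError(f"unknown test {test!r} (expected one of {TESTS})")
            if setting not in SETTINGS:
                raise ValidationError(
                    f"unknown care setting {setting!r} (expected one of {SETTINGS})"
                )
            if not isinstance(amount, (int, float)) or isinstance(amount, bool):
                raise ValidationError(f"cost for {(test, setting)} is not a number: {amount!r}")
            if amount < 0:
                raise ValidationError(f"negative unit cost for {(test, setting)}: {amount}")
        object.__setattr__(self, "costs", dict(self.costs))

    def unit_cost(self, test: str, setting: str) -> float:
        """Return the unit cost for ``(test, setting)``.

        Raises
        ------
        MissingCostError
            If the pair is not priced in this table.
        """
        try:
            return float(self.costs[(test, setting)])
        except KeyError:
            raise MissingCostError(test, setting, self.country) from None

    def has_cost(self, test: str, setting: str) -> bool:
        return (test, setting) in self.costs

    def with_cost(self, test: str, setting: str, amount: float) -> "UnitCostTable":
        """Return a copy of the table with one amount replaced (or added)."""
        costs = dict(self.costs)
        costs[(test, setting)] = float(amount)
        return UnitCostTable(self.country, self.currency, costs)

    def to_frame(self) -> pd.DataFrame:
        """Tests x settings frame for inspection/CSV export; unpriced cells are NaN."""
        frame = pd.DataFrame(index=list(TESTS), columns=list(SETTINGS), dtype=float)
        for (test, setting), amount in self.costs.items():
            frame.loc[test, setting] = amount
        frame.index.name = "test"
        return frame


@dataclass(frozen=True)
class PathwayProbabilities:
    """Branch fractions of the gatekeeper decision tree.

    ``p_positive`` + ``p_uncertain`` + ``p_negative`` must equal one, as must
    the second-line split over the uncertain branch.
    """

    p_positive: float
    p_uncertain: float
    p_negative: float
    uncertain_split: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, frac in (
            ("p_positive", self.p_positive),
            ("p_uncertain", self.p_uncertain),
            ("p_negative", self.p_negative),
        ):
            _check_fraction(name, frac)
        total = self.p_positive + self.p_uncertain + self.p_negative
        if abs(total - 1.0) > PROB_TOL:
            raise ValidationError(f"branch fractions sum to {total!r}, expected 1")
        for test, frac in self.uncertain_split.items():
            if test not in SECOND_LINE_TESTS:
                raise ValidationError(
                    f"unknown second-line test {test!r} (expected one of {SECOND_LINE_TESTS})"
                )
            _check_fraction(f"uncertain_split[{test}]", frac)
        split_total = sum(self.uncertain_split.values())
        if abs(split_total - 1.0) > PROB_TOL:
            raise ValidationError(f"uncertain split sums to {split_total!r}, expected 1")
        object.__setattr__(self, "uncertain_split", dict(self.uncertain_split))


def _check_fraction(name: str, value: float) -> None:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ValidationError(f"{name} is not a number: {value!r}")
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} = {value!r} outside [0, 1]")


# ---------------------------------------------------------------------------
# readers / writers

def load_cost_table(path: str | Path) -> UnitCostTable:
    """Load and validate a per-country unit-cost YAML file."""
    raw = _read_yaml(path)
    for key in ("country", "currency", "costs"):
        if key not in raw:
            raise ConfigError(f"{path}: missing required key {key!r}")
    costs_block = raw["costs"]
    if not isinstance(costs_block, dict):
        raise ConfigError(f"{path}: 'costs' must be a mapping test -> setting -> amount")
    costs: dict[tuple[str, str], float] = {}
    for test, settings in costs_block.items():
        if not isinstance(settings, dict):
            raise ConfigError(f"{path}: costs[{test!r}] must map setting -> amount")
        for setting, amount in settings.items():
            costs[(str(test), str(setting))] = amount
    try:
        return UnitCostTable(str(raw["country"]), str(raw["currency"]), costs)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def load_probabilities(path: str | Path) -> PathwayProbabilities:
    """Load and validate a pathway-proportions YAML file."""
    raw = _read_yaml(path)
    for key in ("p_positive", "p_uncertain", "p_negative", "uncertain_split"):
        if key not in raw:
            raise ConfigError(f"{path}: missing required key {key!r}")
    try:
        return PathwayProbabilities(
            p_positive=raw["p_positive"],
            p_uncertain=raw["p_uncertain"],
            p_negative=raw["p_negative"],
            uncertain_split={str(k): v for k, v in dict(raw["uncertain_split"]).items()},
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def load_cost_config(
    cost_path: str | Path, probabilities_path: str | Path
) -> tuple[UnitCostTable, PathwayProbabilities]:
    """Load a country cost table together with a probabilities file."""
    return load_cost_table(cost_path), load_probabilities(probabilities_path)


def write_cost_table(table: UnitCostTable, path: str | Path) -> None:
    """Write a table back to the YAML config format (round-trip safe)."""
    costs: dict[str, dict[str, float]] = {}
    for (test, setting), amount in table.costs.items():
        costs.setdefault(test, {})[setting] = amount
    doc = {"country": table.country, "currency": table.currency, "costs": costs}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


def write_probabilities(probs: PathwayProbabilities, path: str | Path) -> None:
    doc = {
        "p_positive": probs.p_positive,
        "p_uncertain": probs.p_uncertain,
        "p_negative": probs.p_negative,
        "uncertain_split": dict(probs.uncertain_split),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


def export_csv(table: UnitCostTable, path: str | Path) -> None:
    """Export a loaded table as CSV for inspection."""
    table.to_frame().to_csv(path)


def _read_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return raw


# ---------------------------------------------------------------------------
# bundled data

def bundled_data_path(name: str) -> Path:
    """Path of a bundled data file shipped inside the package."""
    with resources.as_file(resources.files("cmrcost.data") / name) as p:
        return Path(p)


def load_country(key: str) -> UnitCostTable:
    """Load one of the four bundled country tables.

    ``key`` is one of ``germany``, ``united_kingdom``, ``switzerland``,
    ``united_states``.
    """
    try:
        fname = _COUNTRY_FILES[key]
    except KeyError:
        raise ConfigError(
            f"unknown country key {key!r} (expected one of {sorted(_COUNTRY_FILES)})"
        ) from None
    return load_cost_table(bundled_data_path(fname))


def load_all_countries() -> dict[str, UnitCostTable]:
    """All four bundled country tables, keyed by country key."""
    return {key: load_country(key) for key in _COUNTRY_FILES}


def printed_probabilities() -> PathwayProbabilities:
    """The rounded registry proportions as printed: 21% / 6% / 73%,
    second-line split 85/13/2."""
    return load_probabilities(bundled_data_path("probabilities_printed.yaml"))
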