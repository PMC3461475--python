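"""Exception hierarchy for cmrcost.

All errors raised by the package derive from :class:`CmrCostError` so callers
can catch everything model-related with one clause.
"""


class CmrCostError(Exception):
    """Base class for all cmrcost errors."""


class ConfigError(CmrCostError):
    """A config file is missing, malformed, or fails schema validation."""


class ValidationError(ConfigError):
    """A loaded object violates a model invariant (negative cost,
    probabilities not summing to one, fraction outside [0, 1], ...)."""


class MissingCostError(CmrCostError, KeyError):
    """A (test, setting) pair required by a scenario is not priced."""

    def __init__(self, test: str, setting: str, country: str | None = None):
        self.test = test
        self.setting = setting
        self.country = country
        where = f" in table for {country!r}" if country else ""
        super().__init__(f"no unit cost for test {test!r} in setting {setting!r}{where}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class UndefinedPercentageError(CmrCostError, ZeroDivisionError):
    """Percent saving is undefined because the comparator cost is zero."""


class BracketingError(CmrCostError, ValueError):
    """A root-finding bracket does not change sign."""


class CalibrationError(CmrCostError, ValueError):
    """Proportion calibration failed (solution outside [0, 1])."""


class DegenerateSystemError(CalibrationError):
    """The calibration linear system is rank deficient."""


class EmptyCohortError(CmrCostError, ValueError):
    """A cohort simulation was requested with n < 1."""


class InsufficientSampleError(CmrCostError, ValueError):
    """A summary statistic needs more observations than the sample has."""
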