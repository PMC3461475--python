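"""Monte Carlo cohort simulation of patient-level pathways.

Each simulated patient follows the gatekeeper tree: a branch (positive /
uncertain / negative) is drawn from the pathway proportions, an uncertain
patient additionally draws one second-line test from the split, and the
realized cost is the deterministic sum of tariffs along that pathway. Costs
carry no per-patient noise by default — the model is tariff-based, every
patient on the same pathway is reimbursed identically — so the only source
of variance is the multinomial branch draw. An optional lognormal
multiplicative cost-noise hook exists for robustness exploration; it is off
by default and not part of the tariff-based model.

The sample mean is an unbiased Monte Carlo estimate of the analytic
expectation computed by :func:`cmrcost.model.expected_cost_cmr_strategy`,
which is what the simulation is for: validating the closed-form compilation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cost_tables import PathwayProbabilities, UnitCostTable
from .errors import EmptyCohortError, InsufficientSampleError
from .model import Scenario

BRANCHES = ("positive", "uncertain", "negative")


@dataclass(frozen=True)
class CohortSample:
    """Patient-level pathway draws with realized costs.

    ``records`` has one row per patient with columns ``patient_id``,
    ``branch``, ``second_line`` (empty string outside the uncertain branch)
    and ``cost``.
    """

    records: pd.DataFrame
    seed: int
    n: int

    def branch_counts(self) -> dict[str, int]:
        counts = self.records["branch"].value_counts()
        return {branch: int(counts.get(branch, 0)) for branch in BRANCHES}

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


@dataclass(frozen=True)
class CohortSummary:
    mean_cost: float
    standard_error: float
    branch_frequencies: dict[str, float]
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_cost": self.mean_cost,
            "standard_error": self.standard_error,
            "branch_frequencies": dict(self.branch_frequencies),
        }


def pathway_costs(
    table: UnitCostTable, scenario: Scenario
) -> tuple[float, dict[str, float], float]:
    """Deterministic cost of each pathway: (positive, per second-line test, negative)."""
    c_cmr = table.unit_cost("CMR", scenario.cmr_setting)
    positive = c_cmr + table.unit_cost("CXA", scenario.cxa_setting)
    uncertain = {
        test: c_cmr + table.unit_cost(test, scenario.secondline_setting)
        for test in ("SECHO", "CT", "SPECT")
    }
    return positive, uncertain, c_cmr


def simulate_cohort(
    table: UnitCostTable,
    probs: PathwayProbabilities,
    scenario: Scenario,
    n: int,
    seed: int,
    *,
    cost_noise_sd: float | None = None,
) -> CohortSample:
    """Draw ``n`` patient pathways and their realized costs.

    Uses a single ``numpy.random.default_rng(seed)`` generator; the same
    seed reproduces the sample exactly.

    Parameters
    ----------
    cost_noise_sd
        If set, multiplies each realized cost by a lognormal factor with
        the given sigma on the log scale (mean-one). Off by default; the
        tariff-based model has deterministic pathway costs.

    Raises
    ------
    EmptyCohortError
        If ``n < 1``.
    """
    if n < 1:
        raise EmptyCohortError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)

    branch_idx = rng.choice(
        3, size=n, p=[probs.p_positive, probs.p_uncertain, probs.p_negative]
    )
    branch = np.array(BRANCHES, dtype=object)[branch_idx]

    split_tests = list(probs.uncertain_split)
    split_p = [probs.uncertain_split[t] for t in split_tests]
    second_line = np.full(n, "", dtype=object)
    uncertain_mask = branch_idx == 1
    n_uncertain = int(uncertain_mask.sum())
    if n_uncertain:
        second_line[uncertain_mask] = rng.choice(
            np.array(split_tests, dtype=object), size=n_uncertain, p=split_p
        )

    cost_positive, cost_uncertain, cost_negative = pathway_costs(table, scenario)
    cost = np.where(branch_idx == 0, cost_positive, cost_negative).astype(float)
    for test, c in cost_uncertain.items():
        cost[(uncertain_mask) & (second_line == test)] = c

    if cost_noise_sd is not None:
        # mean-one lognormal factor so expectations are preserved
        noise = rng.lognormal(mean=-0.5 * cost_noise_sd**2, sigma=cost_noise_sd, size=n)
        cost = cost * noise

    records = pd.DataFrame(
        {
            "patient_id": np.arange(n, dtype=np.int64),
            "branch": branch,
            "second_line": second_line,
            "cost": cost,
        }
    )
    return CohortSample(records=records, seed=int(seed), n=int(n))


def summarize_cohort(sample: CohortSample) -> CohortSummary:
    """Mean realized cost, its standard error and branch frequencies.

    Raises
    ------
    InsufficientSampleError
        If ``n < 2`` (the standard error needs at least two observations).
    """
    n = sample.n
    if n < 2:
        raise InsufficientSampleError(f"standard error needs n >= 2, got n = {n}")
    cost = sample.records["cost"].to_numpy()
    mean = float(cost.mean())
    se = float(cost.std(ddof=1) / np.sqrt(n))
    freqs = {branch: count / n for branch, count in sample.branch_counts().items()}
    return CohortSummary(mean_cost=mean, standard_error=se, branch_frequencies=freqs, n=n)
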