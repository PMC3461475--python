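# Methods

## The decision model

The model is a two-strategy decision tree evaluated from a health-care
payer perspective: only reimbursed tariffs count, with no modelling of
outcomes, complications, radiation risk, downstream treatment, discounting,
or multi-year horizons. Patients are characterized solely by the category of
their gatekeeper CMR reading — positive, uncertain, or negative — not by
their true disease status; the branch fractions come from a registry cohort
(n = 2,717 consecutive stress-CMR patients with suspected CAD) and therefore
embody a real-world pre-test prevalence rather than a disease model with
sensitivities and specificities.

Pathways and their deterministic costs, within one country's currency:

| branch    | fraction | pathway cost |
|-----------|----------|--------------|
| positive  | `p_pos`  | `c_CMR + c_CXA` (confirmatory angiography) |
| uncertain | `p_unc`  | `c_CMR + c_t` for one second-line test `t` drawn from split `s` |
| negative  | `p_neg`  | `c_CMR` |

The uncertain branch is **terminal**: no cost is added after the second-line
test. This is the only reading consistent with the published per-patient
costs (the registry did not collect the results of the follow-on tests), and
it means the uncertain branch contributes `p_unc · m` with
`m = Σ_t s_t c_t`. The comparator strategy is a single angiography for
every patient, `c_CXA`.

Amounts from different tables are never combined; currency conversion and
tariff derivation from the national catalogues (EBM/DRG, HRG, TARMED, CPT)
are out of scope — the bundled tables hold the 2011 tariffs as published.

## Inputs and their defaults

- **Unit-cost tables** (`src/cmrcost/data/*.yaml`): one file per country,
  integer 2011 tariffs per (test, care setting). A pair absent from the file
  is *unpriced* — asking for it is an error, not zero. The German
  `pre_inpatient` setting exists only for CMR (a same-day admitted scan
  reimbursed under a dedicated public-sector code); pricing other tests
  there would invent tariffs that do not exist.
- **Pathway proportions**: the default is the *calibrated* set
  (`p_pos = 128/619 ≈ 0.20679`, `p_unc ≈ 0.05999`, complement negative),
  recovered as described below. The printed rounded set
  (0.21 / 0.06 / 0.73) ships as an alternative preset
  (`probabilities_printed.yaml`); with it, several compiled cells miss the
  published tables by a few currency units, which is exactly the rounding
  the calibration removes.
- **Second-line split**: SEcho 0.85, CT 0.13, SPECT 0.02, fixed. The split
  multiplies `p_unc` in every formula and cannot be identified separately
  from it, so calibration treats it as known.
- **Scenarios**: the ten published rows — four German (outpatient and
  pre-inpatient CMR × outpatient and inpatient CXA) and two each
  (outpatient/inpatient CXA) for the UK, Switzerland, and the US.
  Second-line tests are outpatient procedures in every scenario.

## Calibration

Each published gatekeeper cost is affine in the unknown fractions:
`cost_i = c_CMR,i + p_pos · c_CXA,i + p_unc · m_i`. Two rows with distinct
CXA settings give a full-rank 2×2 system. The default rows are the two
German pre-inpatient scenarios (published costs 521 and 649): they share
the CMR tariff (393) and differ only in the CXA setting (588 vs 1,207),
giving the best-conditioned system, and they leave every other published
value — eight costs in four currencies and four breakevens — as genuine
out-of-sample checks, which the calibrated fractions reproduce within 0.5%
(costs) and 0.2% (breakevens). With more than two rows the system is solved
by ordinary least squares and per-row residuals are reported; on all four
German rows the residuals stay below 2 currency units, the publication's own
internal rounding noise. Rank deficiency (collinear rows) and solutions
leaving [0, 1] are hard errors, not warnings. No uncertainty is attached to
the calibrated fractions: the patient-level registry data are not available.

## Breakeven and prevalence threshold

Because the gatekeeper expectation is affine in the CMR price, the
cost-neutral price is closed-form, `c* = c_CXA (1 − p_pos) − p_unc · m`,
returned unclamped (it may exceed any realistic tariff). A bracketing root
finder (Brent's method, absolute tolerance 1e-6 currency units) on the cost
difference serves as an independent numerical check; a bracket without a
sign change raises an error rather than guessing. A generic
solve-for-any-tariff interface exists, but only the CMR-price case has a
published anchor — notably, the US breakeven is anchored against *inpatient*
CXA; the tool will also compute the outpatient-CXA breakeven (below the
current 740 USD tariff), which has no published counterpart.

The prevalence threshold solves the same equation for the positive fraction
at a fixed CMR price: `p* = (c_CXA − c_CMR − p_unc · m) / c_CXA`, clamped to
[0, 1]. The uncertain fraction and its split are held fixed while `p_pos`
varies, with the negative fraction absorbing the change; no joint model of
the positive and uncertain fractions is assumed, and this choice is the
simplest one consistent with the decision tree. The gatekeeper saves money
iff `p_pos < p*`; sign coherence (saving > 0 ⇔ tariff headroom > 0 ⇔
`p_pos < p*`) is enforced by tests.

## Synthetic cohorts

The simulator draws each patient's branch from
(`p_pos`, `p_unc`, `p_neg`), a second-line test from the split within the
uncertain branch, and assigns the deterministic pathway cost — it emulates
exactly the multinomial structure the analytic compilation assumes, with a
single `numpy.random.default_rng(seed)` generator per cohort. It does *not*
emulate per-patient tariff variation, regional price differences,
correlations between presentation and pathway, or disease status and test
accuracy; Monte Carlo agreement with the analytic expectation therefore
validates the compilation arithmetic and the sampler, not the realism of
tariffs for any particular population. An optional mean-one lognormal
cost-noise hook exists for robustness exploration and is off by default (the
tariff-based model has deterministic pathway costs). Validation runs use
n = 200,000 (single cohort, 3-standard-error band around the analytic mean,
< 1 s) and 50 seeds × n = 10,000 for the unbiasedness check; both sizes keep
the Monte Carlo error a couple of orders below the quantities compared while
running in seconds.

## Numerical choices

- Full-precision float arithmetic end to end; integer tariffs are exact in
  binary floating point. Rounding — half-up to integer currency units and
  integer percents, matching how the reference tables print — happens only
  in the reporting layer, never inside the model.
- Probability vectors must sum to 1 within 1e-9; calibration rank is tested
  against a relative tolerance of 1e-9 on the design matrix scale.
- Percent saving uses the comparator (CXA-for-all) cost as denominator; this
  is the only convention that reproduces every published percentage
  (50, 25, 23, 46, 50, 48, 51, −8, 65, 11) from the published costs.
- A zero comparator cost makes the percentage undefined and raises, rather
  than returning an infinity.

## Known limitations

- Single-period, payer-perspective, cost-only: no QALYs, ICERs, or outcome
  modelling, by design.
- The published tables are internally inconsistent at the ±2 currency-unit
  level, so reproduction tolerances below ~0.3% are not meaningful; the
  package checks costs/breakevens at 0.5% (0.2% for out-of-sample
  breakevens) and percents at one point after rounding.
- Only CMR is modelled as the gatekeeper; SEcho, CT, or SPECT as first-line
  gatekeepers would need pathway proportions this registry cannot provide.
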