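# Published per-patient costs, percent savings and breakeven reimbursements
# for the ten study scenarios. These printed values are model INPUTS in two
# places: the two German pre-inpatient rows are the calibration rows from
# which the unrounded pathway proportions are recovered, and the full set is
# the reference that `cmrcost reproduce-paper --check` compares against.
n_registry: 2717

# scenario id -> [CMR-strategy cost, CXA-for-all cost], in the country currency
printed_costs:
  germany/outpatient_all:                   [292, 588]
  germany/inpatient_cxa:                    [420, 1207]
  germany/preinpatient_cmr_outpatient_cxa:  [521, 588]
  germany/preinpatient_cmr_inpatient_cxa:   [649, 1207]
  united_kingdom/outpatient_all:            [789, 1055]
  united_kingdom/inpatient_cxa:             [970, 1934]
  switzerland/outpatient_all:               [1984, 2580]
  switzerland/inpatient_cxa:                [2408, 4638]
  united_states/outpatient_all:             [942, 874]
  united_states/inpatient_cxa:              [1308, 2652]

# scenario id -> published percent saving of the CMR strategy
# (negative: CMR strategy more expensive)
printed_percent_savings:
  germany/outpatient_all:                   50
  germany/inpatient_cxa:                    65
  germany/preinpatient_cmr_outpatient_cxa:  11
  germany/preinpatient_cmr_inpatient_cxa:   46
  united_kingdom/outpatient_all:            25
  united_kingdom/inpatient_cxa:             50
  switzerland/outpatient_all:               23
  switzerland/inpatient_cxa:                48
  united_states/outpatient_all:             -8
  united_states/inpatient_cxa:              51

# scenario id -> published breakeven CMR reimbursement (cost-neutral price)
printed_breakeven:
  germany/outpatient_all:                   460
  united_kingdom/outpatient_all:            825
  switzerland/outpatient_all:               2015
  united_states/inpatient_cxa:              2085

# default calibration rows: same CMR price (pre-inpatient, 393), different
# CXA setting -> best-conditioned 2x2 system
calibration_rows:
  - germany/preinpatient_cmr_outpatient_cxa
  - germany/preinpatient_cmr_inpatient_cxa
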