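# US national average reimbursements (CPT, 2011 dollars). Inpatient CXA is
# the outpatient procedure plus one floor-bed hospital day.
country: United States
currency: USD
costs:
  CXA:   {outpatient: 874, inpatient: 2652}
  CMR:   {outpatient: 740}
  SECHO: {outpatient: 303}
  CT:    {outpatient: 446}
  SPECT: {outpatient: 570}
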