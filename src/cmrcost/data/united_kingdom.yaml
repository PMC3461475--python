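# NHS 2009/2010 reference costs by HRG; CMR uses the BSCMR/BSCI suggested
# tariff (the legacy MRI mapping of GBP 170 is not used).
country: United Kingdom
currency: GBP
costs:
  CXA:   {outpatient: 1055, inpatient: 1934}
  CMR:   {outpatient: 558}
  SECHO: {outpatient: 213}
  CT:    {outpatient: 111}
  SPECT: {outpatient: 406}
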