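# German public-sector 2011 tariffs. Outpatient amounts follow the uniform
# value scale, inpatient amounts the DRG system. CMR has no outpatient code
# of its own (thoracic MR used) and a dedicated pre-inpatient code for
# same-day admitted scans; CMR as pre_inpatient exists only for this country.
country: Germany
currency: EUR
costs:
  CXA:   {outpatient: 588, inpatient: 1207}
  CMR:   {outpatient: 164, pre_inpatient: 393}
  SECHO: {outpatient: 94}
  CT:    {outpatient: 165}
  SPECT: {outpatient: 275}
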