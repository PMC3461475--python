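# Swiss 2011 tariffs: TARMED for outpatient procedures, DRG (CHUV Lausanne)
# for the inpatient angiography.
country: Switzerland
currency: CHF
costs:
  CXA:   {outpatient: 2580, inpatient: 4638}
  CMR:   {outpatient: 1420}
  SECHO: {outpatient: 447}
  CT:    {outpatient: 494}
  SPECT: {outpatient: 2183}
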