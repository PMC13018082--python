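# Synthetic representative penetrance parameter set, Netherlands-flavoured.
# Stand-in values (see the UK file for the schema); not transcribed from
# IKNL or any publication. For demonstration and testing only.
population: NL
provenance: |
  Synthetic representative parameter set (Netherlands-flavoured). Same
  construction as the UK set with slightly lower population breast-cancer
  lifetime risk. For demonstration and testing only.
genes:
  BRCA1:
    curves:
      - {cancer: BC,   sex: F,    status: carrier, r: 0.70, mu: 50.0, sigma: 16.0}
      - {cancer: BC,   sex: F,    status: general, r: 0.13, mu: 61.0, sigma: 15.0}
      - {cancer: OC,   sex: F,    status: carrier, r: 0.42, mu: 57.0, sigma: 12.0}
      - {cancer: OC,   sex: F,    status: general, r: 0.018, mu: 62.0, sigma: 13.0}
      - {cancer: PANC, sex: both, status: carrier, r: 0.020, mu: 70.0, sigma: 10.0}
      - {cancer: PANC, sex: both, status: general, r: 0.014, mu: 71.0, sigma: 10.0}
    cbc:
      carrier: 0.025
      general: 0.005
  BRCA2:
    curves:
      - {cancer: BC,   sex: F,    status: carrier, r: 0.67, mu: 52.0, sigma: 16.0}
      - {cancer: BC,   sex: F,    status: general, r: 0.13, mu: 61.0, sigma: 15.0}
      - {cancer: OC,   sex: F,    status: carrier, r: 0.16, mu: 61.0, sigma: 11.0}
      - {cancer: OC,   sex: F,    status: general, r: 0.018, mu: 62.0, sigma: 13.0}
      - {cancer: PANC, sex: both, status: carrier, r: 0.028, mu: 68.0, sigma: 10.0}
      - {cancer: PANC, sex: both, status: general, r: 0.014, mu: 71.0, sigma: 10.0}
    cbc:
      carrier: 0.020
      general: 0.005
  PALB2:
    curves:
      - {cancer: BC,   sex: F,    status: carrier, r: 0.51, mu: 55.0, sigma: 16.0}
      - {cancer: BC,   sex: F,    status: general, r: 0.13, mu: 61.0, sigma: 15.0}
      - {cancer: OC,   sex: F,    status: carrier, r: 0.048, mu: 62.0, sigma: 12.0}
      - {cancer: OC,   sex: F,    status: general, r: 0.018, mu: 62.0, sigma: 13.0}
      - {cancer: PANC, sex: both, status: carrier, r: 0.026, mu: 69.0, sigma: 10.0}
      - {cancer: PANC, sex: both, status: general, r: 0.014, mu: 71.0, sigma: 10.0}
    cbc:
      carrier: 0.012
      general: 0.005
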