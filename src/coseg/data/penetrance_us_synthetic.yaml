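# Synthetic representative penetrance parameter set, US-flavoured.
# Stand-in values (see the UK file for the schema); not transcribed from
# SEER or any publication. For demonstration and testing only.
population: US
provenance: |
  Synthetic representative parameter set (US-flavoured). Same construction
  as the UK set with a slightly older population onset and higher
  pancreatic lifetime risk. For demonstration and testing only.
genes:
  BRCA1:
    curves:
      - {cancer: BC,   sex: F,    status: carrier, r: 0.72, mu: 50.0, sigma: 16.0}
      - {cancer: BC,   sex: F,    status: general, r: 0.13, mu: 63.0, sigma: 15.5}
      - {cancer: OC,   sex: F,    status: carrier, r: 0.44, mu: 58.0, sigma: 12.0}
      - {cancer: OC,   sex: F,    status: general, r: 0.017, mu: 63.0, sigma: 13.0}
      - {cancer: PANC, sex: both, status: carrier, r: 0.022, mu: 70.0, sigma: 10.0}
      - {cancer: PANC, sex: both, status: general, r: 0.017, mu: 72.0, sigma: 10.0}
    cbc:
      carrier: 0.025
      general: 0.005
  BRCA2:
    curves:
      - {cancer: BC,   sex: F,    status: carrier, r: 0.69, mu: 52.0, sigma: 16.0}
      - {cancer: BC,   sex: F,    status: general, r: 0.13, mu: 63.0, sigma: 15.5}
      - {cancer: OC,   sex: F,    status: carrier, r: 0.17, mu: 62.0, sigma: 11.0}
      - {cancer: OC,   sex: F,    status: general, r: 0.017, mu: 63.0, sigma: 13.0}
      - {cancer: PANC, sex: both, status: carrier, r: 0.032, mu: 68.0, sigma: 10.0}
      - {cancer: PANC, sex: both, status: general, r: 0.017, mu: 72.0, sigma: 10.0}
    cbc:
      carrier: 0.020
      general: 0.005
  PALB2:
    curves:
      - {cancer: BC,   sex: F,    status: carrier, r: 0.53, mu: 55.0, sigma: 16.0}
      - {cancer: BC,   sex: F,    status: general, r: 0.13, mu: 63.0, sigma: 15.5}
      - {cancer: OC,   sex: F,    status: carrier, r: 0.050, mu: 63.0, sigma: 12.0}
      - {cancer: OC,   sex: F,    status: general, r: 0.017, mu: 63.0, sigma: 13.0}
      - {cancer: PANC, sex: both, status: carrier, r: 0.030, mu: 69.0, sigma: 10.0}
      - {cancer: PANC, sex: both, status: general, r: 0.017, mu: 72.0, sigma: 10.0}
    cbc:
      carrier: 0.012
      general: 0.005
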