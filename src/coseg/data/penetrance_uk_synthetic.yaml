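# Synthetic representative penetrance parameter set, UK-flavoured.
# Parameters (r = lifetime cumulative risk, mu/sigma = mean/sd of age of
# onset in years, normal truncated at age 0) are stand-ins assembled once
# from field-typical published estimates (meta-analytic carrier lifetime
# risks; registry-style population risks). They are NOT transcribed from
# any registry or publication and must not be used clinically.
population: UK
provenance: |
  Synthetic representative parameter set (UK-flavoured). Carrier lifetime
  risks follow the magnitude of published meta-analytic estimates for
  BRCA1/BRCA2/PALB2 carriers; population risks follow UK-registry-scale
  lifetime risks. CBC rates are constant conditional hazards per year since
  the first breast cancer. For demonstration and testing only.
genes:
  BRCA1:
    curves:
      - {cancer: BC,   sex: F,    status: carrier, r: 0.72, mu: 50.0, sigma: 16.0}
      - {cancer: BC,   sex: F,    status: general, r: 0.14, mu: 62.0, sigma: 15.0}
      - {cancer: OC,   sex: F,    status: carrier, r: 0.44, mu: 58.0, sigma: 12.0}
      - {cancer: OC,   sex: F,    status: general, r: 0.020, mu: 63.0, sigma: 13.0}
      - {cancer: PANC, sex: both, status: carrier, r: 0.021, mu: 70.0, sigma: 10.0}
      - {cancer: PANC, sex: both, status: general, r: 0.016, mu: 72.0, sigma: 10.0}
    cbc:
      carrier: 0.025
      general: 0.005
  BRCA2:
    curves:
      - {cancer: BC,   sex: F,    status: carrier, r: 0.69, mu: 52.0, sigma: 16.0}
      - {cancer: BC,   sex: F,    status: general, r: 0.14, mu: 62.0, sigma: 15.0}
      - {cancer: OC,   sex: F,    status: carrier, r: 0.17, mu: 62.0, sigma: 11.0}
      - {cancer: OC,   sex: F,    status: general, r: 0.020, mu: 63.0, sigma: 13.0}
      - {cancer: PANC, sex: both, status: carrier, r: 0.030, mu: 68.0, sigma: 10.0}
      - {cancer: PANC, sex: both, status: general, r: 0.016, mu: 72.0, sigma: 10.0}
    cbc:
      carrier: 0.020
      general: 0.005
  PALB2:
    curves:
      - {cancer: BC,   sex: F,    status: carrier, r: 0.53, mu: 55.0, sigma: 16.0}
      - {cancer: BC,   sex: F,    status: general, r: 0.14, mu: 62.0, sigma: 15.0}
      - {cancer: OC,   sex: F,    status: carrier, r: 0.050, mu: 63.0, sigma: 12.0}
      - {cancer: OC,   sex: F,    status: general, r: 0.020, mu: 63.0, sigma: 13.0}
      - {cancer: PANC, sex: both, status: carrier, r: 0.028, mu: 69.0, sigma: 10.0}
      - {cancer: PANC, sex: both, status: general, r: 0.016, mu: 72.0, sigma: 10.0}
    cbc:
      carrier: 0.012
      general: 0.005
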