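# Synthetic stand-in for the original 2009-era survival-model penetrances
# (higher carrier lifetime risks, younger onset; BRCA1/BRCA2 only, breast
# and ovarian cancer only). Intended for use with the legacy CBC
# formulation. NOT transcribed from any publication; for demonstration and
# testing only.
population: legacy-NL
provenance: |
  Synthetic stand-in for the original Dutch survival-model parameter set:
  higher carrier lifetime risks and younger onset than current estimates,
  BRCA1/BRCA2 only, breast and ovarian cancer only. Pair with the legacy
  independent-breasts CBC formulation to reproduce historical behaviour.
  For demonstration and testing only.
genes:
  BRCA1:
    curves:
      - {cancer: BC, sex: F, status: carrier, r: 0.80, mu: 48.0, sigma: 14.0}
      - {cancer: BC, sex: F, status: general, r: 0.10, mu: 60.0, sigma: 14.0}
      - {cancer: OC, sex: F, status: carrier, r: 0.60, mu: 54.0, sigma: 12.0}
      - {cancer: OC, sex: F, status: general, r: 0.012, mu: 62.0, sigma: 13.0}
    cbc:
      carrier: 0.020
      general: 0.005
  BRCA2:
    curves:
      - {cancer: BC, sex: F, status: carrier, r: 0.75, mu: 50.0, sigma: 14.0}
      - {cancer: BC, sex: F, status: general, r: 0.10, mu: 60.0, sigma: 14.0}
      - {cancer: OC, sex: F, status: carrier, r: 0.27, mu: 58.0, sigma: 11.0}
      - {cancer: OC, sex: F, status: general, r: 0.012, mu: 62.0, sigma: 13.0}
    cbc:
      carrier: 0.020
      general: 0.005
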