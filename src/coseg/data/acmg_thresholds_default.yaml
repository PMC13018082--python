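# Default LR thresholds mapping co-segregation evidence to ACMG/AMP
# PP1/BS4 strength categories, in the style of the Bayesian points
# framework commonly used for segregation evidence. Entirely
# configuration-driven: replace with your expert panel's cut-points as
# needed. Intervals are [min_lr, next min_lr); a boundary value belongs to
# the higher interval.
categories:
  - {label: BS4_Strong,          min_lr: 0.0}
  - {label: BS4_Moderate,        min_lr: 0.053}
  - {label: BS4_Supporting,      min_lr: 0.23}
  - {label: No_evidence,         min_lr: 0.48}
  - {label: PP1_Supporting,      min_lr: 2.08}
  - {label: PP1_Moderate,        min_lr: 4.33}
  - {label: PP1_Strong,          min_lr: 18.7}
  - {label: PP1_VeryStrong,      min_lr: 350.0}
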