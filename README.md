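# coseg

Survival-based full-pedigree co-segregation likelihood ratios for
classifying variants of uncertain significance (VUS) in *BRCA1*, *BRCA2*
and *PALB2*.

When a rare variant of unknown clinical impact is found in a cancer
family, one line of evidence is how the variant tracks with disease among
relatives: a variant carried by every early-onset breast-cancer case and
absent from healthy elderly relatives looks pathogenic; one that fails to
segregate looks benign. `coseg` quantifies this as a likelihood ratio
(equivalently, a Bayes factor) that plugs directly into ACMG/AMP
classification as PP1 (co-segregation) or BS4 (lack of segregation)
evidence. It is aimed at clinical laboratory geneticists and registry
statisticians working from CanRisk-format pedigrees.

## The model

For a family with phenotypes *Ph*, observed variant test results *G*ₒ, and
a proband known to carry the variant (*G*ₚ = 1), the likelihood ratio is

    LR = P_d(G_o | Ph, G_p = 1) / P_n(G_o | Ph, G_p = 1),

the probability of the observed genotypes under the pathogenic hypothesis
(carriers follow carrier penetrance curves, noncarriers population curves)
over the same probability under the benign hypothesis (phenotypes
independent of genotype). All genotype configurations of the rare dominant
variant are enumerated: founders carry with prior 2q(1−q) and children
inherit Mendelianly; the numerator follows by Bayes' rule from the
configuration-wise phenotype likelihoods.

Each individual contributes survival-likelihood terms per gene-associated
cancer process (female breast, ovarian, pancreatic cancer, per gene):
a diagnosis at age *t* contributes the density *f*(*t*) = *h*(*t*)*S*(*t*),
cancer-free follow-up to age *t* contributes the survival *S*(*t*).
Penetrance is smooth in age: *F*(*t*) = *r*·*F*<sub>norm</sub>(*t*; μ, σ)
with a normal truncated at age 0, where *r* is lifetime risk and μ, σ
locate the age of onset; (*r*, μ, σ) are fitted to 5-year age-specific
incidence rates by least squares on the hazard
*h*(*t*) = *r f*<sub>norm</sub> / (1 − *r F*<sub>norm</sub>). Carrier
incidence is built as population incidence × published age-specific
relative risks. Contralateral breast cancer is modelled conditionally on
the first breast cancer with a constant hazard λ
(*f*<sub>cbc</sub>(*u*) = λe<sup>−λu</sup>), and three modes govern
multiple primaries per individual: keep **all relevant cancers** as
independent processes, censor at the **first diagnosis**, or the default
hybrid **first diagnosis + CBC**. A legacy independent-breasts CBC
formulation is available for reproducing historical analyses.

The bundled per-population parameter files (UK, NL, US, legacy-NL) are
**synthetic representative stand-ins** — see their provenance fields —
suitable for demonstration and testing, not clinical use; supply your own
fitted YAML via `--population path/to/file.yaml` for real analyses.

## Worked example

The package ships a small synthetic demonstration family (nine members,
*BRCA1* variant: three breast-cancer-affected carriers diagnosed at 40–52,
one healthy noncarrier aged 50, untested relatives including an
81-year-old):

```sh
python -c "from importlib import resources; print(resources.files('coseg.data')\
.joinpath('demo_family_synthetic.canrisk').read_text())" > demo.canrisk
coseg run --pedigree demo.canrisk --gene BRCA1 --population UK --out out/
```

prints

```
LR = 3.733  (PP1_Supporting)
```

and writes `out/result.json` plus a text report. The LR of 3.7 means the
observed test results are 3.7 times more probable if the variant is
pathogenic than if it is benign — supporting-level PP1 evidence under the
default Tavtigian-style thresholds (configurable via `--thresholds`).
24 genotype configurations were consistent with the observed results.
The same computation is available as a library call:

```python
from coseg import read_canrisk, load_penetrance_set, compute_lr
ped = read_canrisk("demo.canrisk")
res = compute_lr(ped, load_penetrance_set("UK", "BRCA1"))
print(res.lr)              # 3.7328...
```

LRs from independent families carrying the same variant multiply
(`coseg combine out1/result.json out2/result.json`); penetrance parameters
can be fitted from your own incidence tables with `coseg fit-penetrance`.

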