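# Methods

## Model

`coseg` computes a co-segregation likelihood ratio for a rare,
autosomal-dominant cancer-predisposition variant observed in one family.
Conditioning on the proband carrying the variant, the LR compares the
probability of the observed relatives' test results under the pathogenic
hypothesis (phenotypes depend on genotype through carrier penetrance
curves) against the benign hypothesis (phenotypes independent of
genotype). Both probabilities are sums over complete genotype
configurations:

* founders carry with prior 2q(1−q), q the population allele frequency
  (default 10⁻⁴, configurable); homozygous carriers are ignored (prior
  q² ≈ 10⁻⁸) and carrier × carrier matings use the collapsed 3/4 carrier
  transmission probability;
* children inherit Mendelianly; monozygotic twins share one genotype and
  one transmission term;
* priors are renormalized over all configurations with the proband a
  carrier, so the benign-hypothesis probability of the observations is the
  total normalized prior mass of the consistent configurations, and the
  pathogenic-hypothesis probability follows by Bayes' rule from the
  configuration-wise phenotype likelihoods.

Phenotype likelihoods use the standard survival factorization per cancer
process: density f(t) = h(t)S(t) at a diagnosis age, survival S(t) at the
censoring age (age at last examination, or death — death is treated as
plain censoring; the model is cause-specific). Processes modelled per
gene are those with curves in the penetrance set: female breast and
ovarian cancer for all three genes, pancreatic cancer for both sexes.
Male breast cancer is not modelled by default (no male BC curve is
shipped; adding one to a custom parameter file enables it). Prostate
cancer is deliberately excluded: PSA screening detects many low-risk
tumours that do not reflect genetic risk, and users can rarely filter
those out of a pedigree file. Cancers of unmodelled types are ignored
entirely — they neither contribute terms nor trigger censoring.

### Penetrance

F(t) = r·F_norm(t; μ, σ), the normal truncated at age 0 and renormalized
on [0, ∞), so F(0) = 0 and F(∞) = r exactly. Parameters per
gene × cancer × carrier-status curve:

| parameter | meaning                   | units | constraint |
|-----------|---------------------------|-------|------------|
| r         | lifetime cumulative risk  | —     | (0, 1)     |
| μ         | mean age of onset         | years | (0, 130)   |
| σ         | sd of age of onset        | years | > 0        |

Fitting minimizes the width-weighted sum of squared differences between
observed 5-year incidence rates y_i and the model hazard
h(t_i) = r·f_norm / (1 − r·F_norm) at interval midpoints t_i. Midpoint
evaluation with interval-width weights is unbiased for piecewise-constant
registry data. The noncarrier curve is approximated by the
general-population curve, which is accurate for rare variants.

Carrier incidence tables are constructed as population incidence ×
published age-specific relative risks on the union grid of interval
boundaries; where the relative-risk table ends, RR defaults to 1 for the
raw table, and the fitted smooth curve then governs extrapolation.

### Contralateral breast cancer

CBC is modelled conditionally on the first BC with a constant hazard λ
per year since first diagnosis (observed conditional CBC rates show no
clear trend in time since the first tumour): a CBC at t₂ after BC at t₁
contributes λe^{−λ(t₂−t₁)}; a BC survivor without CBC contributes
e^{−λ(W−t₁)} with W the censoring age. λ is hypothesis-specific (carrier
vs general-population rate). Same-age BC and CBC (bilateral diagnosis in
one year) is allowed; the conditional time is then 0 and the density is
λ. The historical "legacy" formulation instead treats the breasts as
independent processes, replacing f_bc(t₁) by
f_bc(t₁)f_bc(t₂) / (4√(S_bc(t₁)S_bc(t₂))) when a CBC is present and
leaving BC survivors' terms unchanged; it is retained as a compatibility
switch for reproducing historical analyses.

### Multiple-cancer modes

* `all_relevant` — every gene-related diagnosis enters as an independent
  process (each other process keeps running to its own diagnosis or the
  censoring age), CBC handled conditionally;
* `first_diagnosis` — follow-up ends at the first gene-related diagnosis:
  that cancer contributes its density, all other processes their survival
  at that age (ties between same-age diagnoses are broken by cancer-type
  name; the others then enter as survival at that age);
* `first_diagnosis_plus_cbc` (default) — as `first_diagnosis`, but a CBC
  after a first BC is retained and modelled conditionally. This hybrid is
  the default because CBC is the one second primary with solid published
  conditional-risk data; expert-panel practice favouring strict
  first-diagnosis censoring is one flag away.

For a double primary in a carrier, keeping all cancers raises the LR
relative to first-diagnosis censoring whenever carrier hazards dominate
population hazards at the relevant ages; the acceptance checks exercise
this on a BC+OC case.

## Numerical choices

* All per-individual terms and all configuration sums are computed in log
  space with log-sum-exp accumulation; pedigree-wide products underflow
  otherwise.
* Enumeration is depth-first in topological order with zero-probability
  branches pruned; the four needed sums (prior and posterior mass, over
  all and over consistent configurations) accumulate in one pass. When
  only the proband is typed the numerator and denominator accumulate
  identical terms in identical order, so LR = 1 bit-exactly.
* The configuration count is capped at 2²⁶ (structured error advising
  `trim_pedigree`, which iteratively strips childless, untested,
  unaffected leaves censored before age 20 — such leaves change the LR by
  well under 1%).
* Consanguineous matings (parents sharing an ancestor) are detected and
  rejected: explicit enumeration would handle them, but prior
  normalization over inbred configurations has not been validated.
* Penetrance fitting uses bounded trust-region least squares
  (r ∈ (10⁻⁴, 0.999), μ ∈ (20, 100), σ ∈ (2, 40) years) from 8
  deterministic coarse-grid starts, keeping the best; fits pinned at a
  bound are flagged in the result metadata. Noiseless recovery is exact to
  ~10⁻¹¹ relative.
* Degenerate inputs: an unknown age is encoded as censor age 0, whose
  survival contribution is exactly 1 (uninformative); an individual with
  recorded cancers but unknown current age has the censoring age lifted
  to the latest event age (with a warning); a single named parent gets a
  synthesized untested, unaffected co-parent of unknown age so the graph
  stays well-formed without inventing phenotype information.

## Interfaces and parameter sets

Pedigrees are read and written in CanRisk tabular format (version header
`##CanRisk`, `##`-prefixed column row; `BC2` maps to CBC; gene-test
results `P`/`N`/`0` map to carrier/noncarrier/untested; `0` parent ids to
absent). One gene is analysed per run; test results for other genes are
ignored with a warning. Risk-factor and pathology columns are preserved
verbatim on write.

Penetrance sets are per-population YAML files keyed by gene; each carrier
curve must be paired with a general-population curve (the benign
hypothesis needs it), enforced at load. The bundled UK/NL/US and
legacy-NL files are **synthetic representative stand-ins**: magnitudes
follow field-typical published estimates (e.g. carrier lifetime breast-
cancer risks around 0.5–0.7, population around 0.13–0.14; the legacy set
uses the higher risks and younger onsets typical of early estimates), but
no value is transcribed from any registry or publication, and they must
not be used clinically. ACMG thresholds are likewise pure configuration;
the bundled default follows the common Bayesian points-style cut-points
(supporting/moderate/strong/very strong at LR 2.08/4.33/18.7/350 and
reciprocals for the benign direction), with boundary values assigned to
the higher interval.

## Synthetic data generator

`simulate_pedigree` draws 3-generation families (founder couple, Poisson
sibships, married-in spouses, size-capped at 12 by default with a
guaranteed proband lineage; sizes chosen so exhaustive 2ⁿ enumeration
stays instant in tests). Genotypes are drawn exactly from the Mendelian
prior conditioned on the proband carrying, by enumerating and sampling
the conditional distribution — no rejection sampling, so q = 10⁻⁴ costs
nothing. Cancer histories come from the same curves the likelihood uses:
ever-affected with probability r, onset by inverse CDF of the truncated
normal, censoring normal around 45 y (+15 y per older generation, sd 12,
clipped to [18, 95]), CBC exponential after a simulated BC. Under the
benign model phenotypes are drawn from population curves for everyone, so
the LR is a likelihood ratio evaluated at its own null and E[LR] = 1
exactly — the calibration tests check the 500-replicate mean against
three Monte-Carlo standard errors.

What the generator does not emulate: ascertainment beyond proband
carrier status (real families are selected for striking histories),
secular trends and cohort effects, screening-driven early detection,
competing mortality, treatment effects on second cancers, and genotyping
patterns correlated with phenotype. Passing calibration therefore shows
the estimator is self-consistent under its own model, not that the model
is correct for any particular registry population.

## Problem sizes

The test suite and acceptance script use the 9-member demonstration
family, 50 random families of ≤ 10 members for the brute-force oracle,
500 benign-model and 200 pathogenic-model replicates for calibration, and
50 random parameter triples for fit recovery; the whole suite runs in
about a minute on one core.

## Known limitations

* Genotype enumeration is exponential in family size; very large or
  complex pedigrees need trimming. Peeling-style exact algorithms would
  scale better and are a natural future extension.
* No uncertainty measure accompanies the LR; evidence from few families
  should be interpreted cautiously and combined across families.
* The bundled parameter files are demonstrative stand-ins (above).
* Loops from consanguinity are rejected rather than handled.
* Male breast cancer is off by default; prostate cancer is excluded.
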