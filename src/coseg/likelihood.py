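"""Per-individual phenotype likelihood contributions.

Under the survival formulation each gene-associated cancer process
contributes a density term f(t) at the diagnosis age for affected
individuals and a survival term S(t) at the censoring age for unaffected
ones; processes are treated as independent.  Contralateral breast cancer
(CBC) is the exception: it is modelled conditionally on the first breast
cancer through a constant hazard, contributing
f_cbc(t_cbc - t_bc) = lambda * exp(-lambda (t_cbc - t_bc)) when a CBC
occurred and exp(-lambda (t_censor - t_bc)) otherwise.

Three modes govern multiple cancers per individual:

``all_relevant``
    every gene-related diagnosis enters the product (full independence),
    with CBC handled conditionally as above;
``first_diagnosis``
    follow-up ends at the first gene-related diagnosis — that cancer
    contributes its density, every other process its survival at that age;
``first_diagnosis_plus_cbc``
    as ``first_diagnosis``, but a CBC after a first BC is retained and
    modelled conditionally.

An optional legacy formulation reproduces the historical CBC treatment in
which the two breasts were modelled as independent processes:
f_bc(t1) f_bc(t2) / (4 sqrt(S_bc(t1) S_bc(t2))).

All terms are computed and aggregated in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .pedigree import CancerType, Genotype, Individual, Sex
from .penetrance import CARRIER, GENERAL, PenetranceSet

__all__ = [
    "CancerMode",
    "CbcFormulation",
    "Contribution",
    "individual_contribution",
    "legacy_cbc_contribution",
]


class CancerMode(str, Enum):
    ALL_RELEVANT = "all_relevant"
    FIRST_DIAGNOSIS = "first_diagnosis"
    FIRST_DIAGNOSIS_PLUS_CBC = "first_diagnosis_plus_cbc"


class CbcFormulation(str, Enum):
    CONDITIONAL = "conditional"  # exponential conditional hazard
    LEGACY = "legacy_cbc"        # independent-breasts historical term


@dataclass
class Contribution:
    """Log-likelihood of one individual's phenotype under one genotype."""

    log_likelihood: float
    terms: dict[str, float] = field(default_factory=dict)


def legacy_cbc_contribution(t_bc: float, t_cbc: float, pset: PenetranceSet,
                            status: str = CARRIER) -> float:
    """Historical CBC term: f_bc(t1) f_bc(t2) / (4 sqrt(S_bc(t1) S_bc(t2))).

    Derives from treating each breast as an independent process with half
    the total hazard; replaces the first-BC density f_bc(t1) when a CBC at
    ``t_cbc >= t_bc`` is present.  ``status`` selects the carrier or
    general-population BC curve.
    """
    if t_cbc < t_bc:
        raise ValueError("CBC age must not precede the first BC age")
    bc = pset.curve(CancerType.BC, status)
    s1, s2 = float(bc.sf(t_bc)), float(bc.sf(t_cbc))
    if s1 <= 0 or s2 <= 0:
        raise ValueError("BC survival is zero at a diagnosis age: curve saturated")
    return float(bc.pdf(t_bc)) * float(bc.pdf(t_cbc)) / (4.0 * math.sqrt(s1 * s2))


def individual_contribution(ind: Individual, genotype: Genotype,
                            pset: PenetranceSet, mode: CancerMode,
                            cbc: CbcFormulation = CbcFormulation.CONDITIONAL,
                            ) -> Contribution:
    """Phenotype log-likelihood of ``ind`` assuming the given genotype.

    ``genotype`` must be carrier or noncarrier: carriers are evaluated on
    carrier curves, noncarriers on general-population curves (the rare
    variant makes noncarrier and population risks indistinguishable).
    Cancers of types not modelled for the gene are ignored entirely.  An
    individual with no modelled processes (e.g. a male when only female
    cancers are modelled) is uninformative: log-likelihood 0.
    """
    if genotype not in (Genotype.CARRIER, Genotype.NONCARRIER):
        raise ValueError("genotype must be carrier or noncarrier")
    status = CARRIER if genotype == Genotype.CARRIER else GENERAL
    mode = CancerMode(mode)
    cbc = CbcFormulation(cbc)

    processes = pset.processes_for(ind.sex)
    if not processes:
        return Contribution(0.0, {})
    for ev in ind.events:
        if ev.cancer_type not in processes and ev.cancer_type != CancerType.CBC:
            continue
        if ev.cancer_type == CancerType.CBC and CancerType.BC not in processes:
            raise KeyError(f"{ind.id}: CBC observed but BC is not modelled "
                           f"for {pset.gene}")

    ages = {c: ind.event_age(c) for c in processes}
    cbc_age = ind.event_age(CancerType.CBC)
    observed = {c: a for c, a in ages.items() if a is not None}
    terms: dict[str, float] = {}

    if mode == CancerMode.ALL_RELEVANT or not observed:
        # full independence: every process runs to its diagnosis or censoring
        for c in processes:
            curve = pset.curve(c, status)
            if ages[c] is not None:
                terms[c.value] = curve.logpdf(ages[c])
            else:
                terms[c.value] = curve.logsf(ind.censor_age)
        if ages.get(CancerType.BC) is not None:
            _add_cbc_term(terms, ind, status, pset, cbc,
                          window_end=ind.censor_age, cbc_age=cbc_age)
    else:
        # follow-up truncated at the first gene-related diagnosis
        first_cancer = min(observed, key=lambda c: (observed[c], c.value))
        t1 = observed[first_cancer]
        for c in processes:
            curve = pset.curve(c, status)
            if c == first_cancer:
                terms[c.value] = curve.logpdf(t1)
            else:
                terms[c.value] = curve.logsf(t1)
        if mode == CancerMode.FIRST_DIAGNOSIS_PLUS_CBC and first_cancer == CancerType.BC:
            _add_cbc_term(terms, ind, status, pset, cbc,
                          window_end=ind.censor_age, cbc_age=cbc_age)

    return Contribution(sum(terms.values()), terms)


def _add_cbc_term(terms: dict, ind: Individual, status: str, pset: PenetranceSet,
                  cbc: CbcFormulation, window_end: float, cbc_age) -> None:
    """Attach the CBC term given an observed first BC at terms['BC']."""
    if not pset.models_cbc and cbc == CbcFormulation.CONDITIONAL:
        return
    t_bc = ind.event_age(CancerType.BC)
    if cbc == CbcFormulation.LEGACY:
        if cbc_age is not None:
            # the legacy expression replaces f_bc(t_bc) wholesale
            terms["BC"] = math.log(
                legacy_cbc_contribution(t_bc, cbc_age, pset, status))
            terms["CBC"] = 0.0
        return
    model = pset.cbc_model(status)
    if cbc_age is not None:
        terms["CBC"] = model.logpdf(cbc_age - t_bc)
    else:
        terms["CBC"] = model.logsf(max(window_end - t_bc, 0.0))
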