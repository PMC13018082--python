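"""Synthetic pedigree and incidence-table generators.

These generators make the whole pipeline testable without external data:

* :func:`simulate_pedigree` draws a family whose genotypes follow the
  rare-dominant transmission model conditioned on the proband being a
  carrier (sampled exactly, by enumerating the conditional distribution)
  and whose cancer histories are drawn from the very penetrance curves the
  likelihood uses — under the *pathogenic* model carriers follow carrier
  curves, under the *benign* model everyone follows population curves.
  Under the benign model the likelihood ratio is a martingale with mean 1,
  which drives the null-calibration tests.

* :func:`synth_incidence` inverts the penetrance fit: it tabulates the
  model hazard on age bins, optionally with multiplicative noise.

Cancer ages are sampled by inverse-CDF: an individual is ever-affected by a
process with probability r, in which case the onset age follows the
truncated normal; censoring then decides whether the event is observed.
All randomness flows from the ``seed`` in :class:`SimSpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .pedigree import CancerEvent, CancerType, Genotype, Individual, Pedigree, Sex
from .penetrance import CARRIER, GENERAL, IncidenceTable, PenetranceParams, PenetranceSet
from .segregation import _dfs, _logpriors, _prepare

__all__ = ["SimSpec", "simulate_pedigree", "synth_incidence"]


@dataclass
class SimSpec:
    """Study conditions for one simulated family.

    ``model`` selects the generating hypothesis: 'pathogenic' (carriers on
    carrier curves) or 'benign' (everyone on population curves).
    ``genotyping_prob`` is the chance each relative's test result is
    revealed; the proband is always revealed (and is always a carrier).
    Censoring ages are normal around ``censor_mean`` (+15 years per older
    generation), sd ``censor_sd``, clipped to [18, 95].
    """

    gene: str = "BRCA1"
    model: str = "benign"
    generations: int = 3
    mean_children: float = 2.0
    allele_frequency: float = 1e-4
    genotyping_prob: float = 0.9
    censor_mean: float = 45.0
    censor_sd: float = 12.0
    max_members: int = 12
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.allele_frequency < 0.01):
            raise ValueError("allele frequency must lie in (0, 0.01)")
        if not (0 <= self.genotyping_prob <= 1):
            raise ValueError("genotyping_prob must lie in [0, 1]")
        if self.model not in ("pathogenic", "benign"):
            raise ValueError("model must be 'pathogenic' or 'benign'")
        if self.generations < 2:
            raise ValueError("need at least two generations")


def simulate_pedigree(spec: SimSpec, pset: PenetranceSet) -> Pedigree:
    """Draw one family (topology, genotypes, phenotypes) under ``spec``.

    Deterministic for a fixed seed.  The returned pedigree is CanRisk-
    writable and satisfies all Individual invariants (CBC after BC, censor
    age bounding event ages).
    """
    rng = np.random.default_rng(spec.seed)
    ped = _simulate_topology(spec, rng)
    truth = _sample_genotypes(ped, spec.allele_frequency, rng)
    _sample_phenotypes(ped, truth, spec, pset, rng)
    for m in ped.members.values():
        if m.is_proband:
            m.genotype = Genotype.CARRIER
        elif rng.random() < spec.genotyping_prob:
            m.genotype = truth[m.id]
        else:
            m.genotype = Genotype.UNTESTED
    return ped


def _simulate_topology(spec: SimSpec, rng: np.random.Generator) -> Pedigree:
    members: dict[str, Individual] = {}
    counter = [0]
    generation: dict[str, int] = {}

    def new(sex: Sex, gen: int, father=None, mother=None) -> Individual:
        counter[0] += 1
        ind = Individual(id=f"I{counter[0]}", sex=sex,
                         father_id=father, mother_id=mother)
        members[ind.id] = ind
        generation[ind.id] = gen
        return ind

    father = new(Sex.MALE, 0)
    mother = new(Sex.FEMALE, 0)
    couples = [(father, mother)]
    last_gen_kids: list[Individual] = []
    for gen in range(1, spec.generations):
        next_couples = []
        kids_this_gen = []
        for ci, (fa, mo) in enumerate(couples):
            n_kids = 1 + rng.poisson(max(spec.mean_children - 1.0, 0.0))
            for k in range(n_kids):
                # the first couple always gets one child so the proband
                # lineage reaches the final generation despite the size cap
                guaranteed = ci == 0 and k == 0
                if len(members) >= spec.max_members and not guaranteed:
                    break
                sex = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
                kid = new(sex, gen, father=fa.id, mother=mo.id)
                kids_this_gen.append(kid)
                if gen < spec.generations - 1 and \
                        (len(members) < spec.max_members or guaranteed):
                    spouse = new(Sex.MALE if sex == Sex.FEMALE else Sex.FEMALE, gen)
                    pair = (kid, spouse) if kid.sex == Sex.MALE else (spouse, kid)
                    next_couples.append(pair)
        couples = next_couples
        last_gen_kids = kids_this_gen

    proband = next((k for k in last_gen_kids if k.sex == Sex.FEMALE), None)
    if proband is None:
        proband = last_gen_kids[-1]
        proband.sex = Sex.FEMALE
    proband.is_proband = True

    ped = Pedigree(family_id=f"SIM{spec.seed}", members=members, proband_id=proband.id)
    ped._generation = generation  # consumed by phenotype sampling
    return ped


def _sample_genotypes(ped: Pedigree, q: float,
                      rng: np.random.Generator) -> dict[str, Genotype]:
    """Exact draw from P(c | proband carrier) by enumerating the prior."""
    groups, _ = _prepare(ped, max_configs=2 ** 22)
    lq, l1mq = _logpriors(q)
    configs: list[dict[str, Genotype]] = []
    logw: list[float] = []
    _dfs(groups, None, {}, ped.proband_id, lq, l1mq,
         lambda lp, ll, ok, a: (configs.append(dict(a)), logw.append(lp)))
    w = np.exp(np.array(logw) - max(logw))
    idx = rng.choice(len(configs), p=w / w.sum())
    return configs[idx]


def _sample_phenotypes(ped: Pedigree, truth: dict[str, Genotype], spec: SimSpec,
                       pset: PenetranceSet, rng: np.random.Generator) -> None:
    generations = getattr(ped, "_generation", {})
    max_gen = max(generations.values(), default=0)
    for m in ped.members.values():
        gen = generations.get(m.id, max_gen)
        censor = float(np.clip(
            rng.normal(spec.censor_mean + 15.0 * (max_gen - gen), spec.censor_sd),
            18.0, 95.0))
        m.censor_age = round(censor, 1)

        if spec.model == "pathogenic" and truth[m.id] == Genotype.CARRIER:
            status = CARRIER
        else:
            status = GENERAL

        events = []
        for cancer in pset.processes_for(m.sex):
            params = pset.curve(cancer, status)
            if rng.random() >= params.r:
                continue
            t = float(params._dist().ppf(rng.random()))
            if t <= m.censor_age:
                events.append(CancerEvent(cancer, round(max(t, 0.0), 1)))
        bc = next((e for e in events if e.cancer_type == CancerType.BC), None)
        if bc is not None and pset.models_cbc:
            lam = pset.cbc_model(status).rate
            t2 = bc.age + rng.exponential(1.0 / lam)
            if t2 <= m.censor_age:
                events.append(CancerEvent(CancerType.CBC, round(t2, 1)))
        events.sort(key=lambda e: (e.age, e.cancer_type != CancerType.BC))
        m.events = events


def synth_incidence(params: PenetranceParams,
                    bins: Optional[np.ndarray] = None,
                    noise_sd: float = 0.0,
                    seed: Optional[int] = None) -> IncidenceTable:
    """Tabulate the model hazard h(t; r, mu, sigma) on age bins.

    ``bins`` are interval boundaries (default 5-year bins, 20-90).  With
    ``noise_sd`` > 0 the rates are multiplied by lognormal noise
    exp(N(0, noise_sd)), seeded by ``seed``.  The noiseless table is the
    exact forward image of the parameters, so fitting it back recovers
    them.
    """
    if bins is None:
        bins = np.arange(20.0, 95.0, 5.0)
    bins = np.asarray(bins, dtype=float)
    mid = 0.5 * (bins[:-1] + bins[1:])
    rates = params.hazard(mid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rates = rates * np.exp(rng.normal(0.0, noise_sd, size=rates.shape))
    return IncidenceTable(bins[:-1], bins[1:], rates,
                          meta={**params.meta, "source": "synthetic"})
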