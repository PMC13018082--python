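"""Genotype-configuration enumeration and the co-segregation likelihood ratio.

The likelihood ratio compares the probability of the observed family
genotypes G_o given the family phenotypes, conditional on the proband being
a carrier, under the pathogenic versus the benign hypothesis:

    LR = P_d(G_o | Ph_f, G_p = 1) / P_n(G_o | Ph_f, G_p = 1).

Under the pathogenic hypothesis carriers follow carrier penetrance curves
and noncarriers population curves, so by Bayes' rule

    P_d(G_o | Ph, G_p=1) = sum_{c ~ G_o} P(Ph | c) P(c | G_p=1)
                           / sum_{all c} P(Ph | c) P(c | G_p=1),

where c ranges over full genotype configurations (one carrier/noncarrier
assignment per member), "c ~ G_o" means c matches every observed genotype,
and P(c | G_p=1) is the Mendelian transmission prior for a rare dominant
variant (founders carry with probability 2q(1-q)), renormalized over all
configurations with the proband a carrier.  Under the benign hypothesis
phenotypes are independent of genotype, so

    P_n(G_o | Ph, G_p=1) = sum_{c ~ G_o} P(c | G_p=1).

Configurations are enumerated depth-first with zero-probability branches
pruned; all sums run in log space.  When only the proband is genotyped the
two hypotheses coincide and LR = 1 exactly.
"""

from __future__ import annotations

import bisect
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Optional, Sequence

import networkx as nx
import numpy as np
import yaml

from .likelihood import CancerMode, CbcFormulation, individual_contribution
from .pedigree import Genotype, Individual, Pedigree
from .penetrance import PenetranceSet

__all__ = [
    "GenotypeConfig",
    "LrResult",
    "EnumerationError",
    "founder_prior",
    "transmission_prob",
    "enumerate_configs",
    "compute_lr",
    "combine_families",
    "lr_to_acmg",
    "DEFAULT_ALLELE_FREQUENCY",
    "MAX_CONFIGS",
]

DEFAULT_ALLELE_FREQUENCY = 1e-4
MAX_CONFIGS = 2 ** 26

_NEG_INF = float("-inf")


class EnumerationError(RuntimeError):
    """Genotype enumeration cannot proceed (size cap, loops, contradictions)."""


@dataclass
class GenotypeConfig:
    """One full carrier/noncarrier assignment with its normalized log prior."""

    assignment: dict[str, Genotype]
    log_prior: float


@dataclass
class LrResult:
    """The likelihood ratio with diagnostics and the settings that produced it."""

    lr: float
    log_numerator: float
    log_denominator: float
    n_configs: int
    settings: dict = field(default_factory=dict)
    per_individual: dict = field(default_factory=dict)


def founder_prior(allele_frequency: float) -> float:
    """Heterozygous-carrier prior 2q(1-q) for a founder; rare-variant model.

    Homozygous carriers are ignored: with q < 0.01 their q^2 prior is
    negligible and carriers are treated as heterozygous throughout.
    """
    q = allele_frequency
    if not (0 < q < 0.01):
        raise ValueError(f"allele frequency {q} outside (0, 0.01)")
    return 2.0 * q * (1.0 - q)


def transmission_prob(parent_genotypes: Sequence[Genotype],
                      child_genotype: Genotype) -> float:
    """Mendelian transmission for a rare dominant variant.

    Carriers are heterozygous; a carrier × carrier pair produces a carrier
    (heterozygous or homozygous, collapsed) child with probability 3/4.
    """
    k = sum(1 for g in parent_genotypes if g == Genotype.CARRIER)
    p_carrier = (0.0, 0.5, 0.75)[k]
    return p_carrier if child_genotype == Genotype.CARRIER else 1.0 - p_carrier


# ---------------------------------------------------------------------------
# Enumeration machinery
# ---------------------------------------------------------------------------

def _check_structure(ped: Pedigree) -> None:
    g = ped.graph()
    if not nx.is_directed_acyclic_graph(g):
        raise EnumerationError("parent links form a cycle")
    for m in ped.members.values():
        if m.father_id and m.mother_id:
            fa = nx.ancestors(g, m.father_id) | {m.father_id}
            ma = nx.ancestors(g, m.mother_id) | {m.mother_id}
            if fa & ma:
                raise EnumerationError(
                    f"consanguineous mating (parents of {m.id} are blood relatives) "
                    "is not supported")


def _build_groups(ped: Pedigree) -> list[list[Individual]]:
    """Assignment variables: MZ-twin groups share one genotype (and one
    transmission term); everyone else is a singleton.  Returned in an order
    where parents precede children."""
    order = list(nx.topological_sort(ped.graph()))
    order = [i for i in order if i in ped.members]
    seen: set[str] = set()
    groups: list[list[Individual]] = []
    for iid in order:
        if iid in seen:
            continue
        m = ped.members[iid]
        if m.mz_twin_group:
            twins = [t for t in ped.members.values()
                     if t.mz_twin_group == m.mz_twin_group]
            if len({(t.father_id, t.mother_id) for t in twins}) > 1:
                raise EnumerationError(
                    f"MZ twin group {m.mz_twin_group!r} spans different parents")
        else:
            twins = [m]
        groups.append(twins)
        seen.update(t.id for t in twins)
    return groups


class _Accumulator:
    """Online log-sum-exp."""

    __slots__ = ("value",)

    def __init__(self):
        self.value = _NEG_INF

    def add(self, x: float) -> None:
        self.value = float(np.logaddexp(self.value, x))


def _group_log_prior(group: list[Individual], genotype: Genotype,
                     assignment: dict[str, Genotype], log_q_prior: float,
                     log_1m_q_prior: float) -> float:
    """Log prior factor of assigning ``genotype`` to a group, given parents.

    Founders contribute the carrier prior each; a sibling/twin group with
    parents contributes a single transmission term (one meiosis for MZ
    twins).  Returns -inf for impossible assignments.
    """
    rep = group[0]
    if rep.is_founder:
        per = log_q_prior if genotype == Genotype.CARRIER else log_1m_q_prior
        return per * len(group)
    parents = (assignment[rep.father_id], assignment[rep.mother_id])
    p = transmission_prob(parents, genotype)
    return math.log(p) if p > 0 else _NEG_INF


def _dfs(groups, phen, observed, proband_id, log_q_prior, log_1m_q_prior,
         visit):
    """Depth-first walk over genotype assignments, pruning zero-prior branches.

    ``visit(lp, ll, consistent, assignment)`` is called at every complete
    nonzero-prior assignment with the raw log prior, the phenotype
    log-likelihood, and whether the assignment matches all observations.
    """
    assignment: dict[str, Genotype] = {}

    def recurse(idx: int, lp: float, ll: float, consistent: bool):
        if idx == len(groups):
            visit(lp, ll, consistent, assignment)
            return
        group = groups[idx]
        choices = (Genotype.CARRIER,) if any(m.id == proband_id for m in group) \
            else (Genotype.CARRIER, Genotype.NONCARRIER)
        for g in choices:
            f = _group_log_prior(group, g, assignment, log_q_prior, log_1m_q_prior)
            if f == _NEG_INF:
                continue
            ok = consistent and all(
                observed.get(m.id) in (None, g) for m in group)
            dll = sum(phen[m.id][g] for m in group) if phen else 0.0
            for m in group:
                assignment[m.id] = g
            recurse(idx + 1, lp + f, ll + dll, ok)
        for m in group:
            assignment.pop(m.id, None)

    recurse(0, 0.0, 0.0, True)


def _prepare(ped: Pedigree, max_configs: int):
    _check_structure(ped)
    groups = _build_groups(ped)
    n_free = len(groups) - 1  # proband's group is fixed to carrier
    if 2 ** max(n_free, 0) > max_configs:
        raise EnumerationError(
            f"pedigree implies up to 2^{n_free} genotype configurations, above "
            f"the cap of {max_configs}; trim uninformative branches first "
            "(see trim_pedigree)")
    observed = {m.id: m.genotype for m in ped.members.values()
                if m.genotype != Genotype.UNTESTED}
    return groups, observed


def enumerate_configs(pedigree: Pedigree, q: float = DEFAULT_ALLELE_FREQUENCY,
                      max_configs: int = MAX_CONFIGS) -> Iterator[GenotypeConfig]:
    """Yield every genotype configuration consistent with the observations.

    Configurations have nonzero Mendelian prior, match all observed
    genotypes, and fix the proband as a carrier.  ``log_prior`` is
    normalized over *all* nonzero-prior configurations with the proband a
    carrier, so priors of the consistent set sum to
    P_n(G_o | Ph, G_p = 1) <= 1 (and to 1 when only the proband is typed).
    """
    groups, observed = _prepare(pedigree, max_configs)
    lq, l1mq = _logpriors(q)

    z = _Accumulator()
    _dfs(groups, None, observed, pedigree.proband_id, lq, l1mq,
         lambda lp, ll, ok, a: z.add(lp))
    if z.value == _NEG_INF:
        raise EnumerationError("no genotype configuration has positive prior")

    out: list[GenotypeConfig] = []
    _dfs(groups, None, observed, pedigree.proband_id, lq, l1mq,
         lambda lp, ll, ok, a: out.append(
             GenotypeConfig(dict(a), lp - z.value)) if ok else None)
    if not out:
        raise EnumerationError(
            "observed genotypes inconsistent with Mendelian transmission")
    return iter(out)


def _logpriors(q: float) -> tuple[float, float]:
    p = founder_prior(q)
    return math.log(p), math.log1p(-p)


# ---------------------------------------------------------------------------
# The likelihood ratio
# ---------------------------------------------------------------------------

def compute_lr(pedigree: Pedigree, pset: PenetranceSet,
               mode: CancerMode = CancerMode.FIRST_DIAGNOSIS_PLUS_CBC,
               q: float = DEFAULT_ALLELE_FREQUENCY,
               cbc: CbcFormulation = CbcFormulation.CONDITIONAL,
               gene: Optional[str] = None,
               max_configs: int = MAX_CONFIGS) -> LrResult:
    """Co-segregation likelihood ratio for one family.

    Deterministic for fixed inputs; LR > 1 favours pathogenicity.  ``gene``
    is optional and must match ``pset.gene`` when given.  Raises
    :class:`EnumerationError` for oversized pedigrees, loops, or observed
    genotypes that contradict Mendelian transmission.
    """
    if gene is not None and gene != pset.gene:
        raise ValueError(f"gene {gene!r} does not match penetrance set for {pset.gene!r}")
    mode = CancerMode(mode)
    cbc = CbcFormulation(cbc)
    groups, observed = _prepare(pedigree, max_configs)
    lq, l1mq = _logpriors(q)

    phen = {
        m.id: {
            Genotype.CARRIER: individual_contribution(
                m, Genotype.CARRIER, pset, mode, cbc).log_likelihood,
            Genotype.NONCARRIER: individual_contribution(
                m, Genotype.NONCARRIER, pset, mode, cbc).log_likelihood,
        }
        for m in pedigree.members.values()
    }

    z, a, b, c = _Accumulator(), _Accumulator(), _Accumulator(), _Accumulator()
    n_consistent = 0

    def visit(lp, ll, consistent, _assignment):
        nonlocal n_consistent
        z.add(lp)
        b.add(lp + ll)
        if consistent:
            a.add(lp)
            c.add(lp + ll)
            n_consistent += 1

    _dfs(groups, phen, observed, pedigree.proband_id, lq, l1mq, visit)

    if a.value == _NEG_INF:
        raise EnumerationError(
            "observed genotypes inconsistent with Mendelian transmission")
    log_num = c.value - b.value           # log P_d(G_o | Ph, G_p=1)
    log_den = a.value - z.value           # log P_n(G_o | Ph, G_p=1)
    return LrResult(
        lr=math.exp(log_num - log_den),
        log_numerator=log_num,
        log_denominator=log_den,
        n_configs=n_consistent,
        settings={"gene": pset.gene, "population": pset.population,
                  "mode": mode.value, "cbc": cbc.value, "allele_frequency": q},
        per_individual={
            iid: {"log_lik_carrier": v[Genotype.CARRIER],
                  "log_lik_noncarrier": v[Genotype.NONCARRIER],
                  "observed_genotype": pedigree.members[iid].genotype.value}
            for iid, v in phen.items()},
    )


def combine_families(results: Sequence[LrResult]) -> float:
    """Combined LR over independent families carrying the same variant.

    Independent families multiply: the combined LR is exp(sum of log LRs).
    Warns when the per-family settings differ.
    """
    if not results:
        raise ValueError("no results to combine")
    first = results[0].settings
    for r in results[1:]:
        if r.settings != first:
            warnings.warn("combining results computed under different settings",
                          stacklevel=2)
            break
    return math.exp(sum(math.log(r.lr) for r in results))


# ---------------------------------------------------------------------------
# ACMG/AMP evidence mapping
# ---------------------------------------------------------------------------

def lr_to_acmg(lr: float, thresholds_config=None) -> str:
    """Map an LR to a configured ACMG/AMP evidence-strength label.

    ``thresholds_config`` is a YAML path or a parsed list of
    ``{label, min_lr}`` entries with strictly increasing lower bounds
    starting at 0; the label whose interval [min_lr_i, min_lr_{i+1})
    contains ``lr`` is returned, a boundary value going to the higher
    interval.  Defaults to the bundled Tavtigian-style threshold file.
    """
    cats = _load_thresholds(thresholds_config)
    lowers = [c["min_lr"] for c in cats]
    if lowers[0] != 0:
        raise ValueError("threshold intervals must cover (0, inf): first min_lr must be 0")
    if any(b <= a for a, b in zip(lowers, lowers[1:])):
        raise ValueError("threshold intervals overlap: min_lr must strictly increase")
    if lr <= 0:
        raise ValueError("LR must be positive")
    return cats[bisect.bisect_right(lowers, lr) - 1]["label"]


def _load_thresholds(config) -> list[dict]:
    if config is None:
        doc = yaml.safe_load(resources.files("coseg.data")
                             .joinpath("acmg_thresholds_default.yaml").read_text())
    elif isinstance(config, (list, tuple)):
        doc = {"categories": list(config)}
    else:
        with open(config) as fh:
            doc = yaml.safe_load(fh)
    cats = [{"label": str(c["label"]), "min_lr": float(c["min_lr"])}
            for c in doc["categories"]]
    if not cats:
        raise ValueError("no threshold categories configured")
    return sorted(cats, key=lambda c: c["min_lr"])
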