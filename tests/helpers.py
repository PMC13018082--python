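"""Shared test utilities: an independent brute-force LR oracle and scenario
builders.  The oracle enumerates all 2^n genotype vectors with
itertools.product and applies the prior and Bayes formulas directly, staying
independent of the package's pruned depth-first enumeration."""

import itertools
import math

from coseg import (CancerEvent, CancerMode, CancerType, Genotype,
                   individual_contribution, transmission_prob)


def brute_force_lr(ped, pset, mode=CancerMode.ALL_RELEVANT, q=1e-4,
                   cbc="conditional"):
    """Exhaustive 2^n likelihood-ratio summation (independent oracle)."""
    ids = list(ped.members)
    fp = 2 * q * (1 - q)
    contrib = {
        iid: {g: math.exp(individual_contribution(
            ped.members[iid], g, pset, mode, cbc).log_likelihood)
            for g in (Genotype.CARRIER, Genotype.NONCARRIER)}
        for iid in ids
    }
    num_cons = num_all = den_cons = den_all = 0.0
    for combo in itertools.product((Genotype.CARRIER, Genotype.NONCARRIER),
                                   repeat=len(ids)):
        a = dict(zip(ids, combo))
        if a[ped.proband_id] != Genotype.CARRIER:
            continue
        mz = {}
        prior = 1.0
        for iid, g in a.items():
            m = ped.members[iid]
            if m.mz_twin_group is not None:
                mz.setdefault(m.mz_twin_group, []).append(g)
        if any(len(set(gs)) > 1 for gs in mz.values()):
            continue
        counted_mz = set()
        for iid, g in a.items():
            m = ped.members[iid]
            if m.is_founder:
                prior *= fp if g == Genotype.CARRIER else 1 - fp
            elif m.mz_twin_group is not None:
                if m.mz_twin_group in counted_mz:
                    continue
                counted_mz.add(m.mz_twin_group)
                prior *= transmission_prob(
                    (a[m.father_id], a[m.mother_id]), g)
            else:
                prior *= transmission_prob(
                    (a[m.father_id], a[m.mother_id]), g)
        if prior == 0.0:
            continue
        ph = 1.0
        for iid, g in a.items():
            ph *= contrib[iid][g]
        consistent = all(
            ped.members[i].genotype == Genotype.UNTESTED
            or ped.members[i].genotype == a[i] for i in ids)
        den_all += prior
        num_all += prior * ph
        if consistent:
            den_cons += prior
            num_cons += prior * ph
    return (num_cons / num_all) / (den_cons / den_all)


def query_scenario(ped, pset, individual_id, age, affected, genotype,
                   mode=CancerMode.FIRST_DIAGNOSIS_PLUS_CBC):
    """LR with one relative's age, affection status and genotype overridden.

    An affected relative is diagnosed with breast cancer at the given age
    (and censored there); an unaffected one is simply censored at that age.
    """
    from coseg import compute_lr
    p = ped.copy()
    m = p.members[individual_id]
    m.censor_age = float(age)
    m.events = [CancerEvent(CancerType.BC, float(age))] if affected else []
    m.genotype = genotype
    return compute_lr(p, pset, mode=mode).lr
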