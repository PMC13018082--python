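import itertools
import math

import pytest

from coseg import (CancerEvent, CancerMode, CancerType, EnumerationError,
                   Genotype, Individual, Pedigree, Sex, SimSpec,
                   combine_families, compute_lr, enumerate_configs,
                   founder_prior, lr_to_acmg, simulate_pedigree,
                   transmission_prob)

from helpers import brute_force_lr


def trio(proband_genotype=Genotype.CARRIER, dad=Genotype.UNTESTED,
         mum=Genotype.UNTESTED):
    members = {
        "DAD": Individual(id="DAD", sex=Sex.MALE, censor_age=70, genotype=dad),
        "MUM": Individual(id="MUM", sex=Sex.FEMALE, censor_age=68, genotype=mum),
        "KID": Individual(id="KID", father_id="DAD", mother_id="MUM",
                          sex=Sex.FEMALE, censor_age=40, is_proband=True,
                          genotype=proband_genotype),
    }
    return Pedigree(family_id="T", members=members, proband_id="KID")


class TestPriors:
    @pytest.mark.parametrize("q, expected", [
        (0.0001, 1.9998e-4),
        (0.005, 9.95e-3),
    ])
    def test_founder_prior_closed_form(self, q, expected):
        assert founder_prior(q) == pytest.approx(expected, rel=1e-10)

    def test_founder_prior_monotone_and_bounded_domain(self):
        qs = [1e-5, 1e-4, 1e-3, 9e-3]
        priors = [founder_prior(q) for q in qs]
        assert priors == sorted(priors)
        for bad in (0.0, 0.02, -1e-4):
            with pytest.raises(ValueError):
                founder_prior(bad)

    @pytest.mark.parametrize("parents, p_carrier", [
        ((Genotype.NONCARRIER, Genotype.NONCARRIER), 0.0),
        ((Genotype.CARRIER, Genotype.NONCARRIER), 0.5),
        ((Genotype.NONCARRIER, Genotype.CARRIER), 0.5),
        ((Genotype.CARRIER, Genotype.CARRIER), 0.75),
    ])
    def test_transmission_probabilities(self, parents, p_carrier):
        assert transmission_prob(parents, Genotype.CARRIER) == p_carrier
        total = sum(transmission_prob(parents, g)
                    for g in (Genotype.CARRIER, Genotype.NONCARRIER))
        assert total == pytest.approx(1.0)


class TestEnumerate:
    def test_trio_configurations_and_prior_normalization(self):
        # proband fixed carrier leaves 4 parent assignments, one of which
        # (both parents noncarrier) has zero transmission probability
        configs = list(enumerate_configs(trio(), q=1e-4))
        assert len(configs) == 3
        parents = {(c.assignment["DAD"], c.assignment["MUM"]) for c in configs}
        assert (Genotype.NONCARRIER, Genotype.NONCARRIER) not in parents
        assert sum(math.exp(c.log_prior) for c in configs) == pytest.approx(1.0)

    def test_trio_priors_match_exhaustive_formula(self):
        # brute force over all 2^3 assignments with the same prior formula
        q = 1e-4
        fp = founder_prior(q)
        raw = {}
        for d, m, k in itertools.product(
                (Genotype.CARRIER, Genotype.NONCARRIER), repeat=3):
            if k != Genotype.CARRIER:
                continue
            prior = (fp if d == Genotype.CARRIER else 1 - fp) \
                * (fp if m == Genotype.CARRIER else 1 - fp) \
                * transmission_prob((d, m), k)
            if prior > 0:
                raw[(d, m)] = prior
        total = sum(raw.values())
        got = {(c.assignment["DAD"], c.assignment["MUM"]): math.exp(c.log_prior)
               for c in enumerate_configs(trio(), q=q)}
        assert got.keys() == raw.keys()
        for key, prior in raw.items():
            assert got[key] == pytest.approx(prior / total, rel=1e-12)

    def test_obligate_carrier_contradiction_raises(self):
        # both parents observed noncarrier but the proband carries
        with pytest.raises(EnumerationError, match="inconsistent"):
            list(enumerate_configs(trio(dad=Genotype.NONCARRIER,
                                        mum=Genotype.NONCARRIER)))

    def test_size_cap_advises_trimming(self, uk_brca1):
        ped = trio()
        with pytest.raises(EnumerationError, match="trim"):
            compute_lr(ped, uk_brca1, max_configs=2)

    def test_consanguinity_rejected(self, uk_brca1):
        ped = trio()
        # grandchild of DAD/MUM mating with their child's sibling
        ped.members["SIB"] = Individual(id="SIB", father_id="DAD",
                                        mother_id="MUM", sex=Sex.MALE,
                                        censor_age=45)
        ped.members["INCEST"] = Individual(id="INCEST", father_id="SIB",
                                           mother_id="KID", sex=Sex.FEMALE,
                                           censor_age=10)
        with pytest.raises(EnumerationError, match="consanguineous"):
            compute_lr(ped, uk_brca1)


class TestComputeLr:
    def test_only_proband_genotyped_gives_exactly_one(self, uk_brca1,
                                                      demo_pedigree):
        for m in demo_pedigree.members.values():
            if not m.is_proband:
                m.genotype = Genotype.UNTESTED
        res = compute_lr(demo_pedigree, uk_brca1)
        assert res.lr == 1.0

    def test_identical_carrier_and_population_curves_give_one(
            self, demo_pedigree, flat_pset):
        res = compute_lr(demo_pedigree, flat_pset)
        assert res.lr == pytest.approx(1.0, abs=1e-10)

    def test_matches_brute_force_on_demo_family(self, demo_pedigree, uk_brca1):
        for mode in CancerMode:
            expected = brute_force_lr(demo_pedigree, uk_brca1, mode)
            got = compute_lr(demo_pedigree, uk_brca1, mode=mode)
            assert got.lr == pytest.approx(expected, rel=1e-10)
            assert got.lr == pytest.approx(
                math.exp(got.log_numerator - got.log_denominator), rel=1e-12)

    def test_mz_twins_share_genotype_and_one_transmission(self, uk_brca1):
        ped = trio()
        for tid in ("TW1", "TW2"):
            ped.members[tid] = Individual(
                id=tid, father_id="DAD", mother_id="MUM", sex=Sex.FEMALE,
                censor_age=35, mz_twin_group="A",
                events=[CancerEvent(CancerType.BC, 33.0)] if tid == "TW1" else [])
        ped.members["TW1"].genotype = Genotype.CARRIER
        expected = brute_force_lr(ped, uk_brca1, CancerMode.ALL_RELEVANT)
        got = compute_lr(ped, uk_brca1, mode=CancerMode.ALL_RELEVANT).lr
        assert got == pytest.approx(expected, rel=1e-10)
        configs = list(enumerate_configs(ped))
        assert all(c.assignment["TW1"] == c.assignment["TW2"] for c in configs)

    def test_random_small_pedigrees_match_brute_force(self, uk_brca1):
        for seed in range(10):
            ped = simulate_pedigree(
                SimSpec(seed=seed, model="pathogenic", max_members=8,
                        genotyping_prob=0.7), uk_brca1)
            assert len(ped.members) <= 10
            expected = brute_force_lr(ped, uk_brca1, CancerMode.ALL_RELEVANT)
            got = compute_lr(ped, uk_brca1, mode=CancerMode.ALL_RELEVANT).lr
            assert got == pytest.approx(expected, rel=1e-10)

    def test_gene_mismatch_rejected(self, demo_pedigree, uk_brca1):
        with pytest.raises(ValueError, match="does not match"):
            compute_lr(demo_pedigree, uk_brca1, gene="BRCA2")


class TestCombineAndAcmg:
    def test_combination_is_multiplicative(self, demo_pedigree, uk_brca1):
        r = compute_lr(demo_pedigree, uk_brca1)
        assert combine_families([r, r]) == pytest.approx(r.lr ** 2, rel=1e-12)
        assert combine_families([r]) == pytest.approx(r.lr)

    def test_reciprocal_pair_cancels(self, demo_pedigree, uk_brca1):
        r = compute_lr(demo_pedigree, uk_brca1)
        inv = type(r)(lr=1.0 / r.lr, log_numerator=-r.log_numerator,
                      log_denominator=-r.log_denominator, n_configs=r.n_configs,
                      settings=r.settings)
        assert combine_families([r, inv]) == pytest.approx(1.0, abs=1e-12)

    def test_empty_combination_rejected(self):
        with pytest.raises(ValueError):
            combine_families([])

    def test_mixed_settings_warn(self, demo_pedigree, uk_brca1):
        r1 = compute_lr(demo_pedigree, uk_brca1, mode=CancerMode.ALL_RELEVANT)
        r2 = compute_lr(demo_pedigree, uk_brca1, mode=CancerMode.FIRST_DIAGNOSIS)
        with pytest.warns(UserWarning, match="different settings"):
            combine_families([r1, r2])

    @pytest.mark.parametrize("lr, label", [
        (1.0, "No_evidence"),
        (1e6, "PP1_VeryStrong"),
        (0.01, "BS4_Strong"),
        (2.08, "PP1_Supporting"),   # boundary goes to the higher interval
        (18.7, "PP1_Strong"),
    ])
    def test_default_thresholds(self, lr, label):
        assert lr_to_acmg(lr) == label

    def test_bad_threshold_configs_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            lr_to_acmg(1.0, [{"label": "a", "min_lr": 0.5}])
        with pytest.raises(ValueError, match="overlap"):
            lr_to_acmg(1.0, [{"label": "a", "min_lr": 0.0},
                             {"label": "b", "min_lr": 0.0}])
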