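import math

import pytest
from hypothesis import given, settings, strategies as st

from coseg import (CARRIER, GENERAL, CancerEvent, CancerMode, CancerType,
                   CbcFormulation, Genotype, Individual, Sex,
                   individual_contribution, legacy_cbc_contribution)

from conftest import make_toy_pset


def female(events=(), censor=60.0, **kw):
    return Individual(id="X", sex=Sex.FEMALE, events=list(events),
                      censor_age=censor, **kw)


class TestIndividualContribution:
    def test_censor_age_zero_is_uninformative(self, toy_pset):
        ind = female(censor=0.0)
        for g in (Genotype.CARRIER, Genotype.NONCARRIER):
            assert individual_contribution(
                ind, g, toy_pset, CancerMode.ALL_RELEVANT).log_likelihood == 0.0

    def test_double_primary_all_relevant_vs_first_diagnosis(self, toy_pset):
        # BC at 45 then OC at 60: all_relevant keeps both densities, while
        # first_diagnosis censors the OC process at the BC age
        ind = female([CancerEvent(CancerType.BC, 45.0),
                      CancerEvent(CancerType.OC, 60.0)], censor=60.0)
        bc = toy_pset.curve(CancerType.BC, CARRIER)
        ov = toy_pset.curve(CancerType.OC, CARRIER)
        lam = toy_pset.cbc_model(CARRIER).rate

        out = individual_contribution(ind, Genotype.CARRIER, toy_pset,
                                      CancerMode.ALL_RELEVANT)
        expected = (bc.logpdf(45) + ov.logpdf(60) - lam * (60 - 45))
        assert out.log_likelihood == pytest.approx(expected, abs=1e-12)

        out = individual_contribution(ind, Genotype.CARRIER, toy_pset,
                                      CancerMode.FIRST_DIAGNOSIS)
        expected = bc.logpdf(45) + ov.logsf(45)
        assert out.log_likelihood == pytest.approx(expected, abs=1e-12)

    def test_cbc_conditional_hand_computation(self, toy_pset):
        # BC at 40, CBC at 48, censored at 70; lambda = 0.02:
        # f_bc(40) * 0.02 exp(-0.02 * 8) * S_ov(40)
        ind = female([CancerEvent(CancerType.BC, 40.0),
                      CancerEvent(CancerType.CBC, 48.0)], censor=70.0)
        out = individual_contribution(ind, Genotype.CARRIER, toy_pset,
                                      CancerMode.FIRST_DIAGNOSIS_PLUS_CBC)
        bc = toy_pset.curve(CancerType.BC, CARRIER)
        ov = toy_pset.curve(CancerType.OC, CARRIER)
        expected = (float(bc.pdf(40.0)) * 0.02 * math.exp(-0.02 * 8.0)
                    * float(ov.sf(40.0)))
        assert math.exp(out.log_likelihood) == pytest.approx(expected, rel=1e-12)

    def test_bc_survivor_without_cbc_gets_exponential_survival(self, toy_pset):
        ind = female([CancerEvent(CancerType.BC, 40.0)], censor=70.0)
        out = individual_contribution(ind, Genotype.CARRIER, toy_pset,
                                      CancerMode.ALL_RELEVANT)
        assert out.terms["CBC"] == pytest.approx(-0.02 * 30.0)

    def test_noncarrier_uses_population_curves(self, toy_pset):
        ind = female([CancerEvent(CancerType.BC, 45.0)], censor=45.0)
        out = individual_contribution(ind, Genotype.NONCARRIER, toy_pset,
                                      CancerMode.FIRST_DIAGNOSIS)
        bc = toy_pset.curve(CancerType.BC, GENERAL)
        ov = toy_pset.curve(CancerType.OC, GENERAL)
        assert out.log_likelihood == pytest.approx(bc.logpdf(45) + ov.logsf(45))

    def test_male_without_modeled_cancers_is_uninformative(self, toy_pset):
        ind = Individual(id="M", sex=Sex.MALE, censor_age=80.0)
        for g in (Genotype.CARRIER, Genotype.NONCARRIER):
            assert individual_contribution(
                ind, g, toy_pset, CancerMode.ALL_RELEVANT).log_likelihood == 0.0

    def test_first_diagnosis_ignores_later_events(self, toy_pset):
        # metamorphic: anything after the first diagnosis must not matter
        base = female([CancerEvent(CancerType.BC, 45.0)], censor=70.0)
        mutated = female([CancerEvent(CancerType.BC, 45.0),
                          CancerEvent(CancerType.OC, 60.0),
                          CancerEvent(CancerType.CBC, 50.0)], censor=70.0)
        for g in (Genotype.CARRIER, Genotype.NONCARRIER):
            a = individual_contribution(base, g, toy_pset,
                                        CancerMode.FIRST_DIAGNOSIS)
            b = individual_contribution(mutated, g, toy_pset,
                                        CancerMode.FIRST_DIAGNOSIS)
            assert a.log_likelihood == pytest.approx(b.log_likelihood)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(t1=st.floats(10.0, 80.0), dt=st.floats(0.0, 20.0))
    def test_unaffected_contribution_non_increasing_in_censor_age(self, t1, dt):
        pset = make_toy_pset()
        a = individual_contribution(female(censor=t1), Genotype.CARRIER,
                                    pset, CancerMode.ALL_RELEVANT)
        b = individual_contribution(female(censor=t1 + dt), Genotype.CARRIER,
                                    pset, CancerMode.ALL_RELEVANT)
        assert b.log_likelihood <= a.log_likelihood + 1e-12

    def test_identical_curves_make_genotypes_indistinguishable(self, flat_pset):
        ind = female([CancerEvent(CancerType.BC, 45.0)], censor=60.0)
        a = individual_contribution(ind, Genotype.CARRIER, flat_pset,
                                    CancerMode.ALL_RELEVANT)
        b = individual_contribution(ind, Genotype.NONCARRIER, flat_pset,
                                    CancerMode.ALL_RELEVANT)
        assert a.log_likelihood == pytest.approx(b.log_likelihood, abs=1e-12)

    def test_all_relevant_raises_contribution_ratio_for_double_primaries(self, toy_pset):
        # carrier hazards dominate population hazards here, so keeping both
        # densities should increase carrier support relative to censoring
        ind = female([CancerEvent(CancerType.BC, 45.0),
                      CancerEvent(CancerType.OC, 55.0)], censor=55.0)
        def ratio(mode):
            c = individual_contribution(ind, Genotype.CARRIER, toy_pset, mode)
            n = individual_contribution(ind, Genotype.NONCARRIER, toy_pset, mode)
            return c.log_likelihood - n.log_likelihood
        assert ratio(CancerMode.ALL_RELEVANT) >= ratio(CancerMode.FIRST_DIAGNOSIS)

    def test_unmodeled_genotype_rejected(self, toy_pset):
        with pytest.raises(ValueError):
            individual_contribution(female(), Genotype.UNTESTED, toy_pset,
                                    CancerMode.ALL_RELEVANT)


class TestLegacyCbc:
    def test_equal_ages_reduce_to_squared_density_over_survival(self, toy_pset):
        bc = toy_pset.curve(CancerType.BC, CARRIER)
        t = 50.0
        expected = float(bc.pdf(t)) ** 2 / (4.0 * float(bc.sf(t)))
        assert legacy_cbc_contribution(t, t, toy_pset) == pytest.approx(expected)

    def test_matches_direct_recomputation(self, toy_pset):
        bc = toy_pset.curve(CancerType.BC, CARRIER)
        out = legacy_cbc_contribution(45.0, 55.0, toy_pset)
        expected = (float(bc.pdf(45)) * float(bc.pdf(55))
                    / (4.0 * math.sqrt(float(bc.sf(45)) * float(bc.sf(55)))))
        assert out == pytest.approx(expected, rel=1e-12)
        assert out > 0

    def test_cbc_before_bc_rejected(self, toy_pset):
        with pytest.raises(ValueError):
            legacy_cbc_contribution(55.0, 45.0, toy_pset)

    def test_legacy_formulation_replaces_bc_term(self, toy_pset):
        ind = female([CancerEvent(CancerType.BC, 45.0),
                      CancerEvent(CancerType.CBC, 55.0)], censor=70.0)
        out = individual_contribution(ind, Genotype.CARRIER, toy_pset,
                                      CancerMode.ALL_RELEVANT,
                                      cbc=CbcFormulation.LEGACY)
        ov = toy_pset.curve(CancerType.OC, CARRIER)
        expected = math.log(legacy_cbc_contribution(45.0, 55.0, toy_pset)) \
            + ov.logsf(70.0)
        assert out.log_likelihood == pytest.approx(expected, rel=1e-12)
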