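"""Closed-form genotype priors, read mixtures and the genome likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleocontam.model import (
    AsmError, SingleError, SiteData, SiteObservation, TsTvError, TwoError,
    TwoPopDemography, TwoPopLikelihood, dataset_log_likelihood,
    drift_to_years, genotype_probs_two_pop, mixture_probs,
    site_log_likelihood,
)


class TestGenotypeProbs:
    def test_hardy_weinberg_limit(self):
        p = genotype_probs_two_pop(0.3, TwoPopDemography(0.0, 0.0))
        np.testing.assert_allclose(p, [0.49, 0.42, 0.09], atol=1e-12)

    @pytest.mark.parametrize("y", [0.01, 0.2, 0.5, 0.77, 0.99])
    def test_zero_drift_is_hardy_weinberg(self, y):
        p = genotype_probs_two_pop(y, TwoPopDemography(0.0, 0.0))
        np.testing.assert_allclose(p, [(1 - y) ** 2, 2 * y * (1 - y), y ** 2],
                                   atol=1e-12)

    def test_huge_anchor_drift_fixes_ancestral(self):
        p = genotype_probs_two_pop(0.5, TwoPopDemography(30.0, 0.0))
        np.testing.assert_allclose(p, [1.0, 0.0, 0.0], atol=1e-12)

    def test_moderate_drift_closed_form(self):
        # frozen by direct evaluation of the diffusion solution
        p = genotype_probs_two_pop(0.5, TwoPopDemography(0.2, 0.4))
        np.testing.assert_allclose(p, [0.453432, 0.274406, 0.272162], atol=1e-6)

    def test_normalization_and_positivity_on_grid(self):
        taus = [0.0, 0.001, 0.01, 0.1, 1.0, 5.0]
        y = np.arange(0.01, 1.0, 0.01)
        for tc in taus:
            for ta in taus:
                p = genotype_probs_two_pop(y, TwoPopDemography(tc, ta))
                assert np.all(p >= 0.0)
                np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("y", [0.0, 1.0, -0.1, 1.5])
    def test_frequency_outside_open_interval_rejected(self, y):
        with pytest.raises(ValueError):
            genotype_probs_two_pop(y, TwoPopDemography(0.1, 0.1))

    def test_negative_drift_rejected(self):
        with pytest.raises(ValueError):
            TwoPopDemography(-0.1, 0.2)


class TestMixtureProbs:
    def test_pure_endogenous_error_free(self):
        np.testing.assert_allclose(mixture_probs(0.0, 0.0, 0.37), [0.0, 0.5, 1.0])

    def test_full_contamination_is_genotype_independent(self):
        q = mixture_probs(1.0, 0.01, 0.6)
        expect = 0.6 * 0.99 + 0.4 * 0.01
        np.testing.assert_allclose(q, expect)

    def test_heterozygote_value(self):
        q = mixture_probs(0.05, 0.001, 0.8)
        assert q[1] == pytest.approx(0.51497, abs=1e-9)

    @given(r_c=st.floats(0, 1), eps=st.floats(0, 0.499), w=st.floats(0, 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_ordering_below_half_error(self, r_c, eps, w):
        q0, q1, q2 = mixture_probs(r_c, eps, w)
        assert q0 <= q1 + 1e-12 and q1 <= q2 + 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mixture_probs(1.2, 0.0, 0.5)


class TestDriftToYears:
    def test_altai_style_conversion(self):
        assert drift_to_years(0.42, 21_818, 29) == 531_486

    def test_closed_form_and_zero(self):
        assert drift_to_years(1.0, 10_000, 25) == 500_000
        assert drift_to_years(0.0, 10_000, 25) == 0


class TestSiteLogLikelihood:
    def test_empty_site_contributes_zero(self):
        obs = SiteObservation(a=0, d=0, w=0.5, y=0.5)
        gp = genotype_probs_two_pop(0.5, TwoPopDemography(0.3, 0.3))
        assert site_log_likelihood(obs, 0.1, SingleError(0.01), gp) == 0.0

    def test_heterozygote_only_path(self):
        # a=1, d=1 with no error or contamination: only i=1 contributes
        obs = SiteObservation(a=1, d=1, w=0.5, y=0.5)
        gp = genotype_probs_two_pop(0.5, TwoPopDemography(0.0, 0.0))
        ll = site_log_likelihood(obs, 0.0, SingleError(0.0), gp)
        assert ll == pytest.approx(math.log(0.25), abs=1e-12)

    def test_two_ancestral_reads_closed_form(self):
        obs = SiteObservation(a=2, d=0, w=0.4, y=0.4)
        gp = genotype_probs_two_pop(0.4, TwoPopDemography(0.2, 0.1))
        ll = site_log_likelihood(obs, 0.0, SingleError(0.0), gp)
        assert ll == pytest.approx(math.log(gp[0] + 0.25 * gp[1]), abs=1e-12)

    def test_unnormalized_prior_rejected(self):
        obs = SiteObservation(a=1, d=1, w=0.5, y=0.5)
        with pytest.raises(ValueError):
            site_log_likelihood(obs, 0.0, SingleError(0.0), np.array([0.5, 0.5, 0.5]))

    def test_ts_tv_uses_flagged_rate(self):
        gp = genotype_probs_two_pop(0.5, TwoPopDemography(0.1, 0.1))
        ts = SiteObservation(a=3, d=1, w=0.5, y=0.5, is_transition=True)
        tv = SiteObservation(a=3, d=1, w=0.5, y=0.5, is_transition=False)
        err = TsTvError(eps_ts=0.05, eps_tv=0.001)
        assert site_log_likelihood(ts, 0.1, err, gp) == pytest.approx(
            site_log_likelihood(ts, 0.1, SingleError(0.05), gp))
        assert site_log_likelihood(tv, 0.1, err, gp) == pytest.approx(
            site_log_likelihood(tv, 0.1, SingleError(0.001), gp))

    def test_two_error_is_site_level_mixture(self):
        gp = genotype_probs_two_pop(0.3, TwoPopDemography(0.1, 0.2))
        obs = SiteObservation(a=4, d=2, w=0.3, y=0.3)
        err = TwoError(eps1=0.01, eps2=0.2, phi=0.7)
        l1 = site_log_likelihood(obs, 0.05, SingleError(0.01), gp)
        l2 = site_log_likelihood(obs, 0.05, SingleError(0.2), gp)
        expect = math.log(0.7 * math.exp(l1) + 0.3 * math.exp(l2))
        assert site_log_likelihood(obs, 0.05, err, gp) == pytest.approx(expect)

    def test_asm_is_polarization_flip_mixture(self):
        dem = TwoPopDemography(0.1, 0.2)
        gp = genotype_probs_two_pop(0.3, dem)
        gp_flip = genotype_probs_two_pop(0.7, dem)
        obs = SiteObservation(a=4, d=2, w=0.25, y=0.3)
        flipped = SiteObservation(a=2, d=4, w=0.75, y=0.7)
        err = AsmError(eps=0.01, r_asm=0.1)
        l_norm = site_log_likelihood(obs, 0.05, SingleError(0.01), gp)
        l_flip = site_log_likelihood(flipped, 0.05, SingleError(0.01), gp_flip)
        expect = math.log(0.9 * math.exp(l_norm) + 0.1 * math.exp(l_flip))
        assert site_log_likelihood(obs, 0.05, err, gp, dem=dem) == pytest.approx(expect)


class TestDatasetLogLikelihood:
    def test_matches_per_site_loop(self, small_dataset):
        data, truth = small_dataset
        dem = truth["demography"]
        err = truth["error"]
        fast = dataset_log_likelihood(data, truth["r_c"], err, dem)
        loop = 0.0
        for j in range(len(data)):
            obs = SiteObservation(a=int(data.a[j]), d=int(data.d[j]),
                                  w=float(data.w[j]), y=float(data.y[j]),
                                  is_transition=bool(data.is_transition[j]))
            gp = genotype_probs_two_pop(obs.y, dem)
            loop += site_log_likelihood(obs, truth["r_c"], err, gp)
        assert fast == pytest.approx(loop, abs=1e-8)

    @pytest.mark.parametrize("error_kind", ["single", "ts_tv", "two_error", "asm"])
    def test_all_error_variants_match_loop(self, tiny_sites, error_kind):
        errs = {"single": SingleError(0.01),
                "ts_tv": TsTvError(0.05, 0.001),
                "two_error": TwoError(0.01, 0.3, 0.6),
                "asm": AsmError(0.01, 0.05)}
        err = errs[error_kind]
        dem = TwoPopDemography(0.2, 0.3)
        fast = TwoPopLikelihood(tiny_sites, type(err)).loglik(0.1, err, dem)
        loop = sum(
            site_log_likelihood(
                SiteObservation(a=int(tiny_sites.a[j]), d=int(tiny_sites.d[j]),
                                w=float(tiny_sites.w[j]), y=float(tiny_sites.y[j]),
                                is_transition=bool(tiny_sites.is_transition[j])),
                0.1, err, genotype_probs_two_pop(tiny_sites.y[j], dem), dem=dem)
            for j in range(len(tiny_sites)))
        assert fast == pytest.approx(loop, abs=1e-9)

    @given(st.permutations(list(range(6))))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_permutation_invariance(self, order):
        base = SiteData(a=[3, 1, 0, 7, 2, 5], d=[0, 2, 4, 1, 2, 0],
                        w=[0.1, 0.3, 0.5, 0.7, 0.9, 0.42],
                        y=[0.2, 0.4, 0.6, 0.8, 0.15, 0.33])
        perm = base.subset(np.array(order))
        dem = TwoPopDemography(0.3, 0.6)
        err = SingleError(0.002)
        assert dataset_log_likelihood(base, 0.1, err, dem) == pytest.approx(
            dataset_log_likelihood(perm, 0.1, err, dem), abs=1e-10)

    def test_duplication_doubles_loglik(self, tiny_sites):
        dem = TwoPopDemography(0.1, 0.1)
        err = SingleError(0.01)
        single = dataset_log_likelihood(tiny_sites, 0.2, err, dem)
        doubled = SiteData(
            a=np.concatenate([tiny_sites.a, tiny_sites.a]),
            d=np.concatenate([tiny_sites.d, tiny_sites.d]),
            w=np.concatenate([tiny_sites.w, tiny_sites.w]),
            y=np.concatenate([tiny_sites.y, tiny_sites.y]),
            is_transition=np.concatenate([tiny_sites.is_transition] * 2))
        assert dataset_log_likelihood(doubled, 0.2, err, dem) == pytest.approx(
            2 * single, abs=1e-9)

    def test_single_site_equals_site_loglik(self):
        data = SiteData(a=[4], d=[1], w=[0.3], y=[0.4])
        dem = TwoPopDemography(0.2, 0.2)
        obs = SiteObservation(a=4, d=1, w=0.3, y=0.4)
        gp = genotype_probs_two_pop(0.4, dem)
        assert dataset_log_likelihood(data, 0.1, SingleError(0.01), dem) == \
            pytest.approx(site_log_likelihood(obs, 0.1, SingleError(0.01), gp))

    def test_empty_dataset_warns_and_returns_zero(self):
        empty = SiteData(a=[], d=[], w=[], y=[])
        with pytest.warns(UserWarning):
            assert dataset_log_likelihood(empty, 0.1, SingleError(0.01),
                                          TwoPopDemography(0.1, 0.1)) == 0.0
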