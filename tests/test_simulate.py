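"""Synthetic-data generator and Monte-Carlo oracles."""

import numpy as np
import pytest

from paleocontam.model import (SingleError, TsTvError, AsmError,
                               TwoPopDemography, genotype_probs_two_pop,
                               mixture_probs, TwoPopLikelihood)
from paleocontam.simulate import (
    SyntheticScenario, sample_panel_frequency, simulate_dataset,
    simulate_tree_panels, wf_forward_oracle,
)


class TestPanelFrequency:
    def test_two_haploids_always_singleton(self, rng):
        assert np.all(sample_panel_frequency(2, rng, size=50) == 1)

    def test_four_haploids_distribution(self, rng):
        draws = sample_panel_frequency(4, rng, size=60_000)
        freq = np.bincount(draws, minlength=4)[1:] / len(draws)
        np.testing.assert_allclose(freq, [6 / 11, 3 / 11, 2 / 11], atol=0.01)

    def test_neutral_singleton_doubleton_ratio(self, rng):
        draws = sample_panel_frequency(100, rng, size=100_000)
        p1 = np.mean(draws == 1)
        p2 = np.mean(draws == 2)
        assert p1 / p2 == pytest.approx(2.0, abs=0.05)


class TestSimulateDataset:
    def test_no_contamination_no_error_tracks_genotype(self):
        sc = SyntheticScenario(demography=TwoPopDemography(0.0, 5.0), r_c=0.0,
                               error=SingleError(0.0), coverage=10.0,
                               n_sites=2_000, seed=1)
        data, truth = simulate_dataset(sc)
        # tau_A huge: genotypes are nearly all homozygous, so the derived
        # fraction per site must be almost always 0 or 1
        frac = data.d / (data.a + data.d)
        assert np.mean((frac == 0.0) | (frac == 1.0)) > 0.95

    def test_full_contamination_fixed_panel(self):
        sc = SyntheticScenario(demography=TwoPopDemography(0.1, 0.1), r_c=1.0,
                               error=SingleError(0.0), coverage=8.0,
                               n_sites=500, seed=2)
        data, _ = simulate_dataset(sc)
        # every read is a contaminant read drawn at the panel frequency
        frac = (data.d / (data.a + data.d)).mean()
        assert frac == pytest.approx(data.w.mean(), abs=0.02)

    def test_mean_derived_fraction_matches_analytic_mixture(self):
        dem = TwoPopDemography(0.2, 0.3)
        sc = SyntheticScenario(demography=dem, r_c=0.05, error=SingleError(0.001),
                               coverage=30.0, n_sites=30_000, seed=3)
        data, _ = simulate_dataset(sc)
        q = mixture_probs(0.05, 0.001, data.w)
        p = genotype_probs_two_pop(data.y, dem)
        expect = (p * q).sum(axis=1)
        n_frag = (data.a + data.d).sum()
        se = np.sqrt(np.sum(expect * (1 - expect)) +
                     np.var(expect) * (data.a + data.d - 1).sum()) / n_frag
        obs = data.d.sum() / n_frag
        assert abs(obs - expect.mean()) < 5 * max(se, 1e-4)

    def test_deterministic_under_seed(self):
        sc = SyntheticScenario(demography=TwoPopDemography(0.2, 0.2), r_c=0.1,
                               coverage=5.0, n_sites=500, seed=77)
        d1, _ = simulate_dataset(sc)
        d2, _ = simulate_dataset(sc)
        assert np.array_equal(d1.d, d2.d) and np.array_equal(d1.y, d2.y)

    def test_sites_independent(self):
        sc = SyntheticScenario(demography=TwoPopDemography(0.2, 0.2), r_c=0.2,
                               coverage=20.0, n_sites=20_000, seed=8)
        data, _ = simulate_dataset(sc)
        frac = data.d / (data.a + data.d)
        lag1 = np.corrcoef(frac[:-1], frac[1:])[0, 1]
        assert abs(lag1) < 0.02

    def test_profile_likelihood_peaks_at_truth(self):
        sc = SyntheticScenario(demography=TwoPopDemography(0.5, 0.5), r_c=0.25,
                               error=SingleError(0.001), coverage=30.0,
                               n_sites=60_000, seed=12)
        data, _ = simulate_dataset(sc)
        ev = TwoPopLikelihood(data)
        grid = np.arange(0.20, 0.30, 0.002)
        ll = [ev.loglik(float(r), SingleError(0.001), TwoPopDemography(0.5, 0.5))
              for r in grid]
        assert abs(grid[int(np.argmax(ll))] - 0.25) <= 0.01

    def test_deamination_inflates_transition_mismatch(self):
        base = dict(demography=TwoPopDemography(0.0, 0.0), r_c=0.0,
                    error=SingleError(0.001), coverage=30.0, n_sites=40_000,
                    seed=15)
        plain, _ = simulate_dataset(SyntheticScenario(**base))
        deam, _ = simulate_dataset(SyntheticScenario(deamination=True, **base))

        def het_excess(data):
            # fraction of fragments disagreeing with a pure-genotype reading
            frac = data.d / (data.a + data.d)
            return np.mean(np.minimum(frac, 1 - frac)[data.is_transition])

        assert het_excess(deam) > het_excess(plain)

    def test_single_contaminant_increases_overdispersion(self):
        base = dict(demography=TwoPopDemography(0.1, 0.1), r_c=0.5,
                    error=SingleError(0.0), coverage=30.0, n_sites=30_000,
                    seed=19)
        pooled, _ = simulate_dataset(SyntheticScenario(**base))
        single, _ = simulate_dataset(SyntheticScenario(single_contaminant=True, **base))

        def disp(data):
            frac = data.d / (data.a + data.d)
            q = mixture_probs(0.5, 0.0, data.w)
            p = genotype_probs_two_pop(data.y, TwoPopDemography(0.1, 0.1))
            return np.var(frac - (p * q).sum(axis=1))

        assert disp(single) > disp(pooled)

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError):
            SyntheticScenario(demography=TwoPopDemography(0.1, 0.1), coverage=0.0)


class TestWfForwardOracle:
    def test_zero_drift_is_hardy_weinberg(self):
        probs, se = wf_forward_oracle(0.4, TwoPopDemography(0.0, 0.0),
                                      n_pop=500, reps=20_000, seed=1)
        hw = np.array([0.36, 0.48, 0.16])
        assert np.all(np.abs(probs - hw) < np.maximum(3 * se, 0.02))

    def test_large_archaic_drift_kills_heterozygotes(self):
        probs, _ = wf_forward_oracle(0.5, TwoPopDemography(0.1, 3.0),
                                     n_pop=300, reps=20_000, seed=2)
        assert probs[1] < 0.08

    def test_matches_closed_form_at_moderate_drift(self):
        dem = TwoPopDemography(0.2, 0.4)
        probs, se = wf_forward_oracle(0.5, dem, n_pop=1_000, reps=30_000, seed=3)
        exact = genotype_probs_two_pop(0.5, dem)
        assert np.all(np.abs(probs - exact) <= 3 * se)

    def test_empty_bin_fails_loudly(self):
        with pytest.raises(RuntimeError, match="bin"):
            wf_forward_oracle(0.999, TwoPopDemography(0.0, 0.0), n_pop=500,
                              reps=1_000, bin_halfwidth=1e-5, seed=4)


class TestTreePanels:
    def test_deterministic_and_covering(self):
        p1 = simulate_tree_panels(panel_size=20, alpha=0.0, sequence_length=3e5, seed=5)
        p2 = simulate_tree_panels(panel_size=20, alpha=0.0, sequence_length=3e5, seed=5)
        assert np.array_equal(p1["A"], p2["A"])
        for name in "ABCD":
            assert np.all((p1[name] > 0) & (p1[name] < 20))

    def test_admixture_enriches_recipient_clade(self):
        p = simulate_tree_panels(panel_size=20, alpha=0.5, sequence_length=2e6, seed=6)
        arch = p["archaic_genotype"] / 2.0
        ab = (p["A"] + p["B"]) / 40.0
        cd = (p["C"] + p["D"]) / 40.0
        # gene flow from the archaic population into the A/B ancestor makes
        # A/B frequencies track the archaic allele more closely than C/D
        corr_ab = np.corrcoef(arch, ab)[0, 1]
        corr_cd = np.corrcoef(arch, cd)[0, 1]
        assert corr_ab > corr_cd
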