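"""Latent-abundance full conditionals and the count-model fit."""

import numpy as np
import pytest
from scipy.stats import binom, poisson

from commocc import (
    CommunityHyperparams,
    MSOMConfig,
    SurveyDesign,
    CovariateSpec,
    draw_community_params,
    expected_richness,
    expected_richness_under_count_model,
    fit_nmixture,
    full_conditional_N,
    marginal_loglik_site_taxon,
    simulate_count_dataset,
    update_N,
)


def brute_force_pmf(y, lam, p, upper=200):
    Ns = np.arange(int(max(y)), upper)
    w = poisson.pmf(Ns, lam)
    for yj, pj in zip(y, p):
        w = w * binom.pmf(yj, Ns, pj)
    return Ns, w / w.sum()


class TestFullConditionalN:
    def test_perfect_detection_is_degenerate(self):
        support, pmf = full_conditional_N([2, 2], 3.0, [1.0, 1.0])
        assert support[np.argmax(pmf)] == 2
        assert pmf[0] == pytest.approx(1.0)

    def test_poisson_surplus_closed_form(self):
        # y=0, lambda=1, p=0.5: P(N=0) = exp(-0.5)
        support, pmf = full_conditional_N([0], 1.0, [0.5])
        assert support[0] == 0
        assert pmf[0] == pytest.approx(np.exp(-0.5), rel=1e-10)

    @pytest.mark.parametrize(
        "y, lam, p",
        [
            ([3, 1], 4.0, [0.5, 0.5]),
            ([0, 0, 2], 1.5, [0.3, 0.6, 0.8]),
            ([5], 0.7, [0.2]),
        ],
    )
    def test_matches_brute_force_enumeration(self, y, lam, p):
        support, pmf = full_conditional_N(y, lam, p)
        Ns, ref = brute_force_pmf(y, lam, p)
        tv = 0.5 * np.abs(pmf - ref[: len(pmf)]).sum() + 0.5 * ref[len(pmf):].sum()
        assert tv < 1e-8

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            full_conditional_N([0], 0.0, [0.5])
        with pytest.raises(ValueError):
            full_conditional_N([1], 1.0, [1.5])
        with pytest.raises(ValueError):
            full_conditional_N([-1], 1.0, [0.5])


class TestUpdateN:
    def test_perfect_single_replicate(self, rng):
        assert update_N([2], 5.0, [1.0], rng) == 2

    def test_single_replicate_surplus_distribution(self, rng):
        draws = np.array([update_N([1], 2.0, [0.5], rng) for _ in range(5000)])
        assert draws.min() >= 1
        # surplus ~ Poisson(1): mean of N = 2
        assert abs(draws.mean() - 2.0) < 3 * np.sqrt(1.0 / 5000) * 3

    def test_multi_replicate_frequencies_match_pmf(self, rng):
        y, lam, p = [1, 0], 2.0, [0.6, 0.4]
        support, pmf = full_conditional_N(y, lam, p)
        draws = np.array([update_N(y, lam, p, rng) for _ in range(4000)])
        freq = np.array([(draws == n).mean() for n in support[:5]])
        assert np.abs(freq - pmf[:5]).max() < 0.03


class TestOccupancyEquivalence:
    def test_capped_abundance_reduces_to_occupancy_likelihood(self):
        """Truncating N at 1 turns the N-mixture into the occupancy model.

        For one visit: P(y | N<=1) with N ~ truncated Poisson equals the
        occupancy likelihood with psi = P(N=1 | N<=1).
        """
        lam, p = 0.8, 0.6
        w0, w1 = np.exp(-lam), lam * np.exp(-lam)
        psi = w1 / (w0 + w1)
        for y in ([0], [1], [0, 0], [1, 0]):
            pv = [p] * len(y)
            direct = (
                w0 / (w0 + w1) * (0.0 if any(y) else 1.0)
                + w1 / (w0 + w1) * np.prod([pj if yj else 1 - pj for yj, pj in zip(y, pv)])
            )
            occ = np.exp(marginal_loglik_site_taxon(y, psi, pv))
            assert occ == pytest.approx(direct, rel=1e-12)


class TestExpectedRichness:
    def test_hand_examples(self):
        assert expected_richness([0.5, 0.5], 1) == pytest.approx(1.0)
        assert expected_richness([0.9, 0.1], 2) == pytest.approx(1.18)

    def test_monotone_and_bounded(self):
        lam = np.array([3.0, 1.0, 0.2, 0.05])
        vals = [expected_richness(lam, n) for n in (1, 2, 5, 20, 200, 5000)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] <= len(lam)
        assert vals[-1] == pytest.approx(len(lam), abs=1e-6)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            expected_richness([0.0, 0.0], 5)
        with pytest.raises(ValueError):
            expected_richness([1.0], 0)


def count_design(n_visits, reps, n_taxa):
    return SurveyDesign(
        n_sites=n_visits, n_years=1, replicates_per_visit=reps,
        n_taxa_true=n_taxa, n_occ_covariates=0, n_det_covariates=0, primer_levels=1,
    )


class TestFitNmixture:
    def test_rejects_presence_absence_data(self):
        from conftest import make_dataset

        data = make_dataset(np.ones((2, 1, 1), dtype=int))
        with pytest.raises(ValueError):
            fit_nmixture(data, MSOMConfig(n_iter=20, burn_in=10, augment=False))

    def test_recovers_community_hyperparameters(self):
        h = CommunityHyperparams(mu_llam=0.0, sigma_llam=1.0, mu_lp=0.4, sigma_lp=0.8)
        params = draw_community_params(h, 30, 0, 0, seed=1)
        data = simulate_count_dataset(
            params, count_design(40, 3, 30), CovariateSpec(primer_probs=(1.0,)), seed=2
        )
        cfg = MSOMConfig(n_chains=2, n_iter=3000, burn_in=1500, thin=5, augment=False)
        fit = fit_nmixture(data, cfg, seed=3)
        s = fit.summary("mu_llam")
        assert s["lo95"] <= 0.0 <= s["hi95"]
        s = fit.summary("sigma_llam")
        assert s["lo95"] <= 1.0 <= s["hi95"]
        # posterior mean N respects the observed lower bound
        ymax = (data.y * data.mask[:, :, None]).max(axis=1)
        assert (fit.mean_z[:, : data.n_taxa] >= ymax - 1e-9).all()

    def test_near_perfect_detection_pins_latent_abundance(self):
        h = CommunityHyperparams(mu_llam=np.log(3.0), sigma_llam=0.0, mu_lp=8.0, sigma_lp=0.0)
        params = draw_community_params(h, 5, 0, 0, seed=4)
        data = simulate_count_dataset(
            params, count_design(30, 2, 5), CovariateSpec(primer_probs=(1.0,)), seed=5
        )
        cfg = MSOMConfig(n_chains=2, n_iter=1500, burn_in=750, thin=5, augment=False)
        fit = fit_nmixture(data, cfg, seed=6)
        ymax = (data.y * data.mask[:, :, None]).max(axis=1)
        assert np.abs(fit.mean_z[:, :5] - ymax).max() < 0.2

    def test_augmented_absent_taxon_membership_below_prior(self):
        # all-zero augmented taxa should have posterior membership < 0.5
        h = CommunityHyperparams(mu_llam=np.log(2.0), sigma_llam=0.3, mu_lp=1.0, sigma_lp=0.3)
        params = draw_community_params(h, 10, 0, 0, seed=7)
        data = simulate_count_dataset(
            params, count_design(30, 2, 10), CovariateSpec(primer_probs=(1.0,)), seed=8
        )
        cfg = MSOMConfig(n_chains=2, n_iter=1500, burn_in=750, thin=5, augment=True, M=20)
        fit = fit_nmixture(data, cfg, seed=9)
        gamma = fit.get("gamma")
        n_obs = fit.n_observed
        # mean membership of augmented taxa
        aug_mean = (gamma.mean() - n_obs) / (20 - n_obs)
        assert aug_mean < 0.5

    def test_expected_richness_from_fit_is_sane(self):
        h = CommunityHyperparams(mu_llam=0.0, sigma_llam=0.5, mu_lp=1.0, sigma_lp=0.5)
        params = draw_community_params(h, 8, 0, 0, seed=10)
        data = simulate_count_dataset(
            params, count_design(25, 2, 8), CovariateSpec(primer_probs=(1.0,)), seed=11
        )
        cfg = MSOMConfig(n_chains=2, n_iter=1000, burn_in=500, thin=5, augment=False)
        fit = fit_nmixture(data, cfg, seed=12)
        small = expected_richness_under_count_model(fit, 5)
        large = expected_richness_under_count_model(fit, 500)
        assert small["mean"] < large["mean"] <= 8.0
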