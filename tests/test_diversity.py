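"""Diversity arithmetic: collapses, dissimilarity, aggregation, reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from commocc import (
    CommunityMatrix,
    MSOMConfig,
    aggregate_taxa,
    corrected_matrices,
    fit_msom,
    observed_matrix,
    pairwise_dissimilarity,
    percent_increase,
    resolution_dissimilarity_contrast,
)
from commocc.diversity import mean_pairwise_dissimilarity
from conftest import make_dataset


def cm(values, taxa=None):
    values = np.asarray(values)
    sites = [f"s{i}" for i in range(values.shape[0])]
    taxa = taxa or [f"t{k}" for k in range(values.shape[1])]
    return CommunityMatrix(values, sites, taxa)


class TestObservedMatrix:
    def test_any_detection_collapse(self):
        y = np.array([[[0], [0], [1]], [[0], [0], [0]]])
        m = observed_matrix(make_dataset(y))
        assert m.values[:, 0].tolist() == [1, 0]

    def test_masked_visits_excluded(self):
        y = np.zeros((3, 2, 1), dtype=int)
        y[0, 0, 0] = 1
        mask = np.array([[1, 1], [0, 0], [1, 0]], dtype=bool)
        m = observed_matrix(make_dataset(y, mask=mask))
        assert m.values.shape[0] == 2  # fully masked visit dropped

    def test_two_by_two_hand_collapse(self):
        y = np.array(
            [[[1, 0], [0, 0]], [[0, 1], [0, 1]]]
        )  # visits x replicates x taxa
        m = observed_matrix(make_dataset(y))
        assert m.values.tolist() == [[1, 0], [0, 1]]


class TestCorrectedMatrices:
    def test_latent_alpha_dominates_observed(self):
        rng = np.random.default_rng(0)
        y = (rng.random((10, 2, 6)) < 0.3).astype(int)
        data = make_dataset(y)
        fit = fit_msom(
            data,
            MSOMConfig(n_chains=2, n_iter=600, burn_in=300, thin=10, augment=False, store_z=True),
            seed=1,
        )
        obs = observed_matrix(data)
        for m in corrected_matrices(fit, data):
            assert (m.alpha >= obs.alpha).all()

    def test_missing_z_draws_give_instructive_error(self):
        y = np.ones((4, 1, 2), dtype=int)
        data = make_dataset(y)
        fit = fit_msom(
            data, MSOMConfig(n_chains=2, n_iter=200, burn_in=100, thin=5, augment=False), seed=2
        )
        with pytest.raises(ValueError, match="store_z"):
            next(corrected_matrices(fit, data))


class TestPairwiseDissimilarity:
    def test_identical_rows_are_zero(self):
        d, _ = pairwise_dissimilarity(cm([[1, 0, 1], [1, 0, 1]]))
        assert d[0, 1] == 0

    def test_disjoint_rows_are_one(self):
        d, _ = pairwise_dissimilarity(cm([[1, 1, 0, 0], [0, 0, 1, 1]]))
        assert d[0, 1] == 1

    def test_jaccard_hand_example(self):
        # A={1,2,3}, B={2,3,4}: jaccard distance = 1 - 2/4
        d, _ = pairwise_dissimilarity(cm([[1, 1, 1, 0], [0, 1, 1, 1]]), "jaccard")
        assert d[0, 1] == pytest.approx(0.5)

    def test_sorensen_hand_example(self):
        d, _ = pairwise_dissimilarity(cm([[1, 1, 1, 0], [0, 1, 1, 1]]), "sorensen")
        assert d[0, 1] == pytest.approx(1 - 4 / 6)

    def test_empty_site_flagged_and_maximal(self):
        d, empty = pairwise_dissimilarity(cm([[0, 0], [1, 0], [0, 0]]))
        assert empty.tolist() == [True, False, True]
        assert d[0, 1] == 1 and d[0, 2] == 0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(m=arrays(np.int8, (4, 6), elements=st.integers(0, 1)))
    def test_metric_properties_and_ordering(self, m):
        mat = cm(m)
        dj, _ = pairwise_dissimilarity(mat, "jaccard")
        ds, _ = pairwise_dissimilarity(mat, "sorensen")
        for d in (dj, ds):
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0)
            assert ((d >= -1e-12) & (d <= 1 + 1e-12)).all()
        assert (dj >= ds - 1e-12).all()


class TestAggregateTaxa:
    def taxonomy(self):
        return pd.DataFrame(
            {
                "genus": ["g1", "g2", "g3"],
                "family": ["fA", "fA", "fB"],
            },
            index=pd.Index(["g1", "g2", "g3"], name="taxon_id"),
        )

    def test_presence_is_or_over_members(self):
        m = cm([[1, 0, 0], [0, 1, 0], [0, 0, 1]], taxa=["g1", "g2", "g3"])
        fam = aggregate_taxa(m, self.taxonomy(), "family")
        assert fam.taxon_labels == ["fA", "fB"]
        assert fam.values.tolist() == [[1, 0], [1, 0], [0, 1]]

    def test_family_prevalence_dominates_members(self):
        rng = np.random.default_rng(1)
        vals = (rng.random((10, 3)) < 0.4).astype(int)
        m = cm(vals, taxa=["g1", "g2", "g3"])
        fam = aggregate_taxa(m, self.taxonomy(), "family")
        prev = fam.values.mean(axis=0)
        assert prev[0] >= vals[:, 0].mean() and prev[0] >= vals[:, 1].mean()

    def test_aggregation_idempotent(self):
        m = cm([[1, 0, 1], [0, 1, 0]], taxa=["g1", "g2", "g3"])
        fam = aggregate_taxa(m, self.taxonomy(), "family")
        tax2 = pd.DataFrame(
            {"genus": ["fA", "fB"], "family": ["fA", "fB"]},
            index=pd.Index(["fA", "fB"], name="taxon_id"),
        )
        fam2 = aggregate_taxa(fam, tax2, "family")
        assert (fam2.values == fam.values).all()

    def test_unmapped_taxon_raises(self):
        m = cm([[1, 0]], taxa=["g1", "gX"])
        with pytest.raises(ValueError):
            aggregate_taxa(m, self.taxonomy(), "family")

    def test_count_dataset_aggregation_sums(self):
        y = np.array([[[2, 3, 1]]])
        data = make_dataset(y, mode="count")
        tax = pd.DataFrame(
            {"genus": ["t000", "t001", "t002"], "family": ["fA", "fA", "fB"]},
            index=pd.Index(["t000", "t001", "t002"], name="taxon_id"),
        )
        agg = aggregate_taxa(data, tax, "family")
        assert agg.y[0, 0].tolist() == [5, 1]


class TestResolutionContrast:
    def test_identical_matrices_zero_contrast(self):
        g = cm([[1, 0], [0, 1]])
        assert resolution_dissimilarity_contrast(g, g) == 0.0

    def test_hand_toy_full_contrast(self):
        # two genera in one family, disjoint between sites:
        # genus jaccard = 1, family jaccard = 0
        g = cm([[1, 0], [0, 1]], taxa=["g1", "g2"])
        f = cm([[1], [1]], taxa=["fA"])
        assert resolution_dissimilarity_contrast(g, f) == float("inf")
        # with one extra shared family the family-level mean is positive
        g2 = cm([[1, 0, 1], [0, 1, 0]], taxa=["g1", "g2", "g3"])
        f2 = cm([[1, 1], [1, 0]], taxa=["fA", "fB"])
        got = resolution_dissimilarity_contrast(g2, f2)
        dg = mean_pairwise_dissimilarity(g2)
        df = mean_pairwise_dissimilarity(f2)
        assert got == pytest.approx(100 * (dg - df) / df)
        assert got > 0

    def test_genus_rank_at_least_as_dissimilar(self):
        rng = np.random.default_rng(2)
        taxa = [f"g{i}" for i in range(12)]
        fams = [f"f{i % 4}" for i in range(12)]
        tax = pd.DataFrame({"genus": taxa, "family": fams}, index=pd.Index(taxa, name="taxon_id"))
        vals = (rng.random((8, 12)) < 0.3).astype(int)
        g = cm(vals, taxa=taxa)
        f = aggregate_taxa(g, tax, "family")
        assert mean_pairwise_dissimilarity(g) >= mean_pairwise_dissimilarity(f) - 1e-9


class TestPercentIncrease:
    @pytest.mark.parametrize(
        "est, obs, expected",
        [(95, 74, 28), (130, 109, 19), (360, 263, 37), (100, 100, 0)],
    )
    def test_reported_rounding(self, est, obs, expected):
        assert percent_increase(est, obs) == expected

    def test_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            percent_increase(10, 0)


class TestBetaCorrectionSummary:
    def test_perfect_detection_leaves_beta_unchanged(self):
        from commocc import beta_correction_summary

        rng = np.random.default_rng(5)
        y = (rng.random((8, 3, 10)) < 0.4).astype(int)
        y = np.repeat(y.max(axis=1)[:, None, :], 3, axis=1)  # every replicate sees all
        data = make_dataset(y)
        fit = fit_msom(
            data,
            MSOMConfig(n_chains=2, n_iter=800, burn_in=400, thin=10,
                       augment=False, store_z=True),
            seed=6,
        )
        out = beta_correction_summary(fit, data)
        # with detections identical across replicates, detection is inferred
        # near-perfect, so corrected beta stays close to observed
        assert abs(out["difference_mean"]) < 0.1
        assert 0 <= out["corrected_mean"] <= 1

    def test_imperfect_detection_inflates_observed_turnover(self):
        from commocc import (
            CommunityHyperparams, CovariateSpec, SurveyDesign,
            beta_correction_summary, draw_community_params, simulate_dataset,
        )

        h = CommunityHyperparams(mu_lpsi=0.0, sigma_lpsi=0.5, mu_lp=-1.0, sigma_lp=0.5)
        params = draw_community_params(h, 20, 0, 0, seed=7)
        design = SurveyDesign(
            n_sites=12, n_years=1, replicates_per_visit=2, n_taxa_true=20,
            n_occ_covariates=0, n_det_covariates=0, primer_levels=1,
        )
        data = simulate_dataset(params, design, CovariateSpec(primer_probs=(1.0,)), seed=8)
        fit = fit_msom(
            data,
            MSOMConfig(n_chains=2, n_iter=1500, burn_in=750, thin=10,
                       augment=False, store_z=True),
            seed=9,
        )
        out = beta_correction_summary(fit, data)
        # low detectability: observed dissimilarity should exceed corrected
        assert out["difference_mean"] > 0
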