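"""Null-model engine: margins, tolerances, stressor, composition test, power."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from commocc import (
    DesignPoint,
    MetacommunitySim,
    apply_stressor,
    build_baseline,
    calibrate_turnover,
    make_tolerances,
    manyglm_test,
    permute_fixed_margins,
    power_curve,
    sample_detection,
)


class TestBuildBaseline:
    def test_saturated_occupancy_fills_matrix(self):
        sim = build_baseline(np.ones(5), 5, 10, seed=1)
        assert (sim.matrix == 1).all()

    def test_column_means_match_psi(self):
        sim = build_baseline(np.full(3, 0.3), 3, 5000, seed=2)
        half = 2.576 * np.sqrt(0.3 * 0.7 / 5000)
        assert np.abs(sim.matrix.mean(axis=0) - 0.3).max() < half

    def test_seed_determinism(self):
        a = build_baseline({"mu": -1, "sigma": 1}, 20, 10, seed=3)
        b = build_baseline({"mu": -1, "sigma": 1}, 20, 10, seed=3)
        assert (a.matrix == b.matrix).all() and (a.psi == b.psi).all()

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            build_baseline(np.ones(1), 0, 5)


class TestPermuteFixedMargins:
    def test_margins_exactly_preserved(self, rng):
        m = (rng.random((20, 50)) < 0.3).astype(np.int8)
        out = permute_fixed_margins(m, 2000, seed=1)
        assert (out.sum(axis=0) == m.sum(axis=0)).all()
        assert (out.sum(axis=1) == m.sum(axis=1)).all()

    def test_zero_swaps_is_identity(self, rng):
        m = (rng.random((5, 8)) < 0.5).astype(np.int8)
        assert (permute_fixed_margins(m, 0, seed=1) == m).all()

    def test_two_by_two_stays_in_margin_class(self):
        m = np.array([[1, 0], [0, 1]], dtype=np.int8)
        states = set()
        for s in range(40):
            out = permute_fixed_margins(m, 5, seed=s)
            states.add(tuple(out.ravel()))
            assert out.sum(axis=0).tolist() == [1, 1]
            assert out.sum(axis=1).tolist() == [1, 1]
        # both members of the margin class are reachable
        assert states == {(1, 0, 0, 1), (0, 1, 1, 0)}

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            permute_fixed_margins(np.array([[2, 0], [0, 1]]), 1)


class TestCalibrateTurnover:
    def test_zero_target_means_no_swaps(self):
        sim = build_baseline({"mu": -1, "sigma": 1}, 30, 10, seed=1)
        assert calibrate_turnover(sim, 0.0)["n_swaps"] == 0

    def test_turnover_nondecreasing_in_swaps(self):
        sim = build_baseline({"mu": -0.8, "sigma": 1}, 100, 20, seed=2)
        out = calibrate_turnover(sim, 0.5, seed=3, n_rep=8)
        achieved = list(out["grid"].values())
        # averaged over repeats, turnover grows then plateaus
        assert achieved[0] == 0.0
        diffs = np.diff(achieved)
        assert (diffs > -0.03).all()
        assert achieved[-1] > achieved[1]

    def test_full_randomization_matches_independent_margin_draws(self):
        # oracle: turnover between two independent heavy shuffles of the
        # same matrix estimates the within-margin-class expectation
        sim = build_baseline(np.full(200, 0.3), 200, 30, seed=4)
        rng = np.random.default_rng(5)
        from commocc.power import _within_site_turnover

        ours = np.mean([
            _within_site_turnover(
                sim.matrix.astype(bool),
                permute_fixed_margins(sim.matrix, 3000, rng.integers(2**31)).astype(bool),
            )
            for _ in range(5)
        ])
        oracle = np.mean([
            _within_site_turnover(
                permute_fixed_margins(sim.matrix, 3000, rng.integers(2**31)).astype(bool),
                permute_fixed_margins(sim.matrix, 3000, rng.integers(2**31)).astype(bool),
            )
            for _ in range(5)
        ])
        assert abs(ours - oracle) < 0.02


class TestMakeTolerances:
    def test_perfect_positive_correlation_preserves_ranks(self):
        psi = np.random.default_rng(1).uniform(0, 1, 50)
        tol = make_tolerances(psi, 1.0, seed=2)
        assert (np.argsort(tol.tolerance) == np.argsort(psi)).all()

    def test_perfect_negative_correlation_reverses_ranks(self):
        psi = np.random.default_rng(3).uniform(0, 1, 50)
        tol = make_tolerances(psi, -1.0, seed=4)
        assert (np.argsort(tol.tolerance) == np.argsort(psi)[::-1]).all()

    def test_zero_correlation_is_near_zero(self):
        psi = np.random.default_rng(5).uniform(0, 1, 360)
        tol = make_tolerances(psi, 0.0, seed=6)
        rho, _ = spearmanr(psi, tol.tolerance)
        assert abs(rho) < 0.1

    def test_intermediate_rho_approximately_achieved(self):
        psi = np.random.default_rng(7).uniform(0, 1, 360)
        tol = make_tolerances(psi, 0.6, seed=8)
        rho, _ = spearmanr(psi, tol.tolerance)
        assert abs(rho - 0.6) < 0.12


class TestApplyStressor:
    def _sim(self, seed=1):
        return build_baseline({"mu": -0.5, "sigma": 1}, 50, 20, seed=seed)

    def test_zero_severity_is_identity(self):
        sim = self._sim()
        tol = make_tolerances(sim.psi, 0.0, seed=2)
        out = apply_stressor(sim, tol, 0.0, seed=3)
        assert (out.matrix == sim.matrix).all()

    def test_exact_occurrence_count_removed(self):
        sim = self._sim()
        total = sim.matrix.sum()
        tol = make_tolerances(sim.psi, 0.0, seed=4)
        out = apply_stressor(sim, tol, 0.2, seed=5)
        assert out.matrix.sum() == total - int(round(0.2 * total))

    def test_fully_tolerant_taxon_untouched(self):
        sim = self._sim()
        tol_vals = np.zeros(sim.gamma)
        tol_vals[0] = 1.0
        from commocc import ToleranceProfile

        tol = ToleranceProfile(tolerance=tol_vals, rho=0.0)
        out = apply_stressor(sim, tol, 0.3, seed=6)
        assert (out.matrix[:, 0] == sim.matrix[:, 0]).all()

    def test_removals_shift_toward_intolerant_taxa(self):
        sim = self._sim()
        tol_vals = np.linspace(0, 1, sim.gamma)
        from commocc import ToleranceProfile

        out = apply_stressor(sim, ToleranceProfile(tolerance=tol_vals, rho=0.0), 0.3, seed=7)
        removed = (sim.matrix - out.matrix).sum(axis=0)
        lost_intolerant = removed[: sim.gamma // 2].sum()
        lost_tolerant = removed[sim.gamma // 2 :].sum()
        assert lost_intolerant > lost_tolerant

    def test_invalid_severity(self):
        sim = self._sim()
        tol = make_tolerances(sim.psi, 0.0, seed=8)
        with pytest.raises(ValueError):
            apply_stressor(sim, tol, 1.5)


class TestSampleDetection:
    def test_perfect_detection_reproduces_presence(self):
        sim = build_baseline({"mu": 0, "sigma": 1}, 30, 10, seed=1)
        y = sample_detection(sim, np.ones(30), 2, seed=2)
        assert (y == sim.matrix[:, None, :]).all()

    def test_zero_detection_gives_empty_data(self):
        sim = build_baseline({"mu": 0, "sigma": 1}, 30, 10, seed=3)
        assert sample_detection(sim, np.zeros(30), 3, seed=4).sum() == 0

    def test_triplicate_detection_closed_form(self):
        # p=0.5, 3 replicates: site-level detection = 1 - 0.5^3 among occupied
        sim = build_baseline(np.ones(1), 1, 5000, seed=5)
        y = sample_detection(sim, np.array([0.5]), 3, seed=6)
        frac = y.max(axis=1).mean()
        target = 1 - 0.5**3
        half = 2.576 * np.sqrt(target * (1 - target) / 5000)
        assert abs(frac - target) < half


class TestManyglmTest:
    def test_single_taxon_hand_deviance(self):
        # detected 2/2 sites in A, 0/2 in B: LR = -8 ln 0.5 ~ 5.545
        A = np.array([[1], [1]])
        B = np.array([[0], [0]])
        res = manyglm_test(A, B, n_resamples=49, seed=1)
        assert res["statistic"] == pytest.approx(-8 * np.log(0.5), rel=1e-10)

    def test_identical_groups_are_null(self):
        m = np.array([[1, 0, 1], [0, 1, 1]])
        res = manyglm_test(m, m, n_resamples=99, seed=2)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == 1.0

    def test_strong_shift_detected(self, rng):
        A = (rng.random((10, 60)) < 0.6).astype(int)
        B = (rng.random((10, 60)) < 0.2).astype(int)
        assert manyglm_test(A, B, n_resamples=199, seed=3)["p_value"] < 0.01

    def test_requires_two_sites_per_group(self):
        with pytest.raises(ValueError):
            manyglm_test(np.array([[1]]), np.array([[0], [1]]))

    def test_null_rejection_rate_is_calibrated(self):
        # light version of the type-I check: 200 null comparisons
        rng = np.random.default_rng(4)
        hits = 0
        n_runs = 200
        for _ in range(n_runs):
            psi = 1 / (1 + np.exp(-rng.normal(-1.0, 1.0, 60)))
            A = (rng.random((10, 60)) < psi).astype(int)
            B = (rng.random((10, 60)) < psi).astype(int)
            hits += manyglm_test(A, B, 199, rng.integers(2**31))["p_value"] <= 0.05
        assert 0.01 <= hits / n_runs <= 0.10


class TestPowerCurve:
    def test_total_removal_always_detected(self):
        res = power_curve(
            [DesignPoint(n_sites=8, replicates=3, detection_preset="dna_genus")],
            [1.0],
            n_sim=20,
            seed=1,
            gamma=80,
            n_resamples=99,
        )
        assert res.power[0, 0] > 0.99

    def test_minimum_detectable_interpolation(self):
        res = power_curve(
            [DesignPoint(n_sites=8, replicates=1, detection_preset="dna_genus")],
            [0.0, 1.0],
            n_sim=10,
            seed=2,
            gamma=60,
            n_resamples=99,
        )
        mds = res.minimum_detectable_severity()
        assert 0.0 < mds[0] <= 1.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            power_curve([], [0.5])


class TestYearlyBaselines:
    def test_zero_effect_keeps_psi_constant(self):
        from commocc import yearly_baselines

        years = yearly_baselines({"mu": -1, "sigma": 1}, 40, 10, 3, 0.0, seed=1)
        assert len(years) == 3
        assert all((y.psi == years[0].psi).all() for y in years)

    def test_year_effects_shift_occupancy_probabilities(self):
        from commocc import yearly_baselines

        years = yearly_baselines(np.full(100, 0.4), 100, 20, 3, 1.5, seed=2)
        # each year's occupancy vector is a distinct perturbation of the base
        assert not (years[0].psi == years[1].psi).all()
        for y in years:
            assert ((y.psi > 0) & (y.psi < 1)).all()
            assert np.isin(y.matrix, (0, 1)).all()
        # the community-mean shift is zero-centred: averages stay near base
        grand = np.mean([y.psi.mean() for y in years])
        assert 0.25 < grand < 0.65
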