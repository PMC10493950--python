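"""Synthetic-data generators: determinism and ground-truth fidelity."""

import numpy as np
import pytest

from hydrophylo import comparative, simulate as sim, trees as htrees
from hydrophylo.simulate import (GroundTruth, piecewise_gmin,
                                 simulate_climate, simulate_drydown_images,
                                 simulate_mass_series, simulate_phylogeny,
                                 simulate_trait_climate, simulate_traits_bm,
                                 vulnerability_logistic)

from conftest import brute_force_vcv


class TestGroundTruth:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GroundTruth(true_p50=1.0)
        with pytest.raises(ValueError):
            GroundTruth(true_lambda=1.5)
        with pytest.raises(ValueError):
            GroundTruth(event_log=[(3, 0)])


class TestTraitsBM:
    def test_lambda_zero_sister_tips_uncorrelated(self, tree8):
        labels = htrees.tip_labels(tree8)
        n_rep = 2000
        draws = np.array([
            list(simulate_traits_bm(tree8, 1.0, 0.0, 0.0, seed=r).values())
            for r in range(n_rep)])
        # every off-diagonal pair should have ~zero covariance
        C = np.cov(draws, rowvar=False)
        off = C[~np.eye(8, dtype=bool)]
        se = 1.0 / np.sqrt(n_rep)  # sd of sample cov of two unit normals
        assert np.all(np.abs(off) < 3 * se)

    def test_sigma_to_zero_collapses_to_root(self, tree8):
        vals = simulate_traits_bm(tree8, 1e-12, 3.7, 1.0, seed=0)
        assert np.allclose(list(vals.values()), 3.7, atol=1e-4)

    def test_lambda_one_covariance_matches_independent_enumeration(self, tree8):
        sigma2 = 0.8
        n_rep = 4000
        draws = np.array([
            list(simulate_traits_bm(tree8, sigma2, 0.0, 1.0, seed=r).values())
            for r in range(n_rep)])
        emp = np.cov(draws, rowvar=False)
        Vb, labels_b = brute_force_vcv(tree8)
        assert labels_b == list(simulate_traits_bm(tree8, 1, 0, 1, 0))
        target = sigma2 * Vb
        rel = np.linalg.norm(emp - target) / np.linalg.norm(target)
        assert rel < 0.05

    def test_deterministic(self, tree8):
        a = simulate_traits_bm(tree8, 1.0, 0.0, 0.6, seed=9)
        b = simulate_traits_bm(tree8, 1.0, 0.0, 0.6, seed=9)
        assert a == b


class TestClimate:
    def test_identity_corr_uncorrelated(self):
        eye = np.eye(5)
        clim = simulate_climate(5000, target_corr=eye, seed=1)
        corr = np.corrcoef(clim.to_numpy(), rowvar=False)
        assert np.all(np.abs(corr[~np.eye(5, dtype=bool)]) < 0.05)

    def test_target_correlation_recovered(self):
        C = np.eye(5)
        C[2, 3] = C[3, 2] = 0.9  # maxT-minT
        clim = simulate_climate(5000, target_corr=C, seed=2)
        r = np.corrcoef(clim["maxT"], clim["minT"])[0, 1]
        assert abs(r - 0.9) < 0.03

    def test_deterministic_and_ranges(self):
        a = simulate_climate(14, seed=3)
        b = simulate_climate(14, seed=3)
        assert a.equals(b)
        assert list(a.columns) == ["MAT", "MAP", "maxT", "minT", "Pdq"]

    def test_non_pd_rejected(self):
        C = np.full((5, 5), 0.99)
        np.fill_diagonal(C, 1.0)
        C[0, 1] = C[1, 0] = -0.99  # infeasible combination
        with pytest.raises(ValueError, match="positive definite"):
            simulate_climate(10, target_corr=C, seed=0)


class TestTraitClimate:
    def test_zero_beta_zero_noise_gives_zero_trait(self, tree8):
        clim = simulate_climate(8, seed=4)
        table, truth = simulate_trait_climate(tree8, clim, (0, 0, 0), 0.0,
                                              0.0, seed=0)
        assert np.allclose(table["trait"], 0.0)

    def test_ols_recovers_beta_with_iid_residuals(self, tree32):
        # lam_resid = 0: PGLS at fixed lambda 0 must recover beta within 3 SE
        clim = simulate_climate(32, seed=5)
        beta = (2.0, -1.5, 0.8)
        table, truth = simulate_trait_climate(tree32, clim, beta, 0.0, 0.04,
                                              seed=6)
        model = comparative.PGLS.from_dataframe(
            table, "trait", ["pc1", "subgenus"], tree32)
        fit = model.fit(lambda_mode=0.0)
        assert abs(fit.params["pc1"] - beta[1]) < 3 * fit.bse["pc1"]
        # generator codes the clade factor as Eucalyptus = 1; the model
        # dummy-codes Symphyomyrtus = 1, so the intercept absorbs beta[2]
        # and the dummy coefficient flips sign
        name = "subgenus[Symphyomyrtus]"
        assert abs(fit.params[name] - (-beta[2])) < 3 * fit.bse[name]
        assert abs(fit.params["Intercept"] - (beta[0] + beta[2])) < \
            3 * fit.bse["Intercept"]

    def test_mismatched_rows_rejected(self, tree8):
        clim = simulate_climate(9, seed=0)
        with pytest.raises(ValueError, match="rows"):
            simulate_trait_climate(tree8, clim, (0, 0, 0), 0.0, 1.0, 0)

    def test_deterministic(self, tree8):
        clim = simulate_climate(8, seed=4)
        t1, _ = simulate_trait_climate(tree8, clim, (1, 2, 3), 0.5, 1.0, 7)
        t2, _ = simulate_trait_climate(tree8, clim, (1, 2, 3), 0.5, 1.0, 7)
        assert t1.equals(t2)


class TestDrydownImages:
    def test_logistic_midpoint(self):
        assert vulnerability_logistic(-5.0, -5.0, 50.0) == pytest.approx(50.0)

    def test_event_area_non_decreasing_and_complete(self):
        stack, trace, truth = simulate_drydown_images(
            p50=-5.0, height=64, width=64, n_frames=60, noise_sd=0.0,
            shrink_events=0, seed=1)
        # cumulative bright area never shrinks and all events fire
        bright = (stack.frames > 15000).sum(axis=(1, 2))
        assert np.all(np.diff(bright) >= 0)
        assert bright[-1] == sum(px for _, px in truth.event_log)
        assert truth.event_log[0][0] >= 1  # nothing in frame 0

    def test_psi_schedule_linear_and_sampling_intervals(self):
        stack, trace, _ = simulate_drydown_images(
            p50=-4.0, n_frames=40, noise_sd=0.0, seed=0)
        assert np.allclose(np.diff(stack.frame_times), 180.0)
        assert np.allclose(np.diff(trace.times)[:-1], 600.0)
        slope = np.polyfit(trace.times, trace.psi, 1)
        resid = trace.psi - np.polyval(slope, trace.times)
        assert np.max(np.abs(resid)) < 1e-12

    def test_deterministic(self):
        a, _, _ = simulate_drydown_images(p50=-5.0, n_frames=30,
                                          noise_sd=200, seed=5)
        b, _, _ = simulate_drydown_images(p50=-5.0, n_frames=30,
                                          noise_sd=200, seed=5)
        assert np.array_equal(a.frames, b.frames)

    def test_p50_outside_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_drydown_images(p50=-9.0, psi_start=-1.0, psi_end=-8.0)


class TestMassSeries:
    def test_stomatal_equals_gmin_is_linear(self):
        series, truth = simulate_mass_series(
            gmin_by_T={25.0: 5.0}, temps=[25.0], initial_stomatal_g=5.0,
            noise_sd_mass=0.0, seed=0)
        m = series[0].masses
        resid = m - np.polyval(np.polyfit(series[0].times, m, 1),
                               series[0].times)
        assert np.max(np.abs(resid)) < 1e-9

    def test_mass_non_increasing_before_noise(self):
        series, _ = simulate_mass_series(noise_sd_mass=0.0, seed=0)
        for s in series:
            assert np.all(np.diff(s.masses) <= 0)

    def test_noise_preserves_mean_decrement(self):
        clean, _ = simulate_mass_series(noise_sd_mass=0.0, temps=[32.0], seed=3)
        total = clean[0].masses[0] - clean[0].masses[-1]
        noisy_totals = []
        for r in range(300):
            noisy, _ = simulate_mass_series(noise_sd_mass=0.0005,
                                            temps=[32.0], seed=r)
            noisy_totals.append(noisy[0].masses[0] - noisy[0].masses[-1])
        se = 0.0005 * np.sqrt(2) / np.sqrt(300)
        assert abs(np.mean(noisy_totals) - total) < 4 * se

    def test_rh_near_100_gives_vanishing_loss(self):
        series, _ = simulate_mass_series(rh=99.99, temps=[30.0],
                                         noise_sd_mass=0.0, seed=0)
        loss = series[0].masses[0] - series[0].masses[-1]
        ref, _ = simulate_mass_series(rh=40.0, temps=[30.0],
                                      noise_sd_mass=0.0, seed=0)
        ref_loss = ref[0].masses[0] - ref[0].masses[-1]
        assert loss < 1e-3 * ref_loss

    def test_rh_100_rejected(self):
        with pytest.raises(ValueError, match="100"):
            simulate_mass_series(rh=100.0)

    def test_piecewise_gmin_breakpoint(self):
        T = np.array([25.0, 36.0, 48.0])
        g = piecewise_gmin(T, 5.0, 36.0, 0.5)
        np.testing.assert_allclose(g, [5.0, 5.0, 11.0])


def test_phylogeny_alias_depth_one():
    tree = simulate_phylogeny(5, seed=3)
    V, _ = htrees.phylo_covariance(tree, 1.0)
    assert np.allclose(np.diag(V), 1.0)
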