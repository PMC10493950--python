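"""Comparative statistics: K, lambda, PGLS, PCA, correlation, loess."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from hypothesis import given, settings, strategies as st

from hydrophylo import comparative, simulate as sim, trees as htrees
from hydrophylo.comparative import (PGLS, PagelLambda, blomberg_k, bonferroni,
                                    climate_pca, cooks_distance, loess_smooth,
                                    pearson_correlation, phylo_signal,
                                    signal_permutation_test)
from hydrophylo.trees import phylo_covariance, tip_labels, write_tree


class TestBlombergK:
    def test_direct_formula_on_fixed_four_taxon_tree(self, balanced4):
        trait = {"A": 1.2, "B": 0.9, "C": -0.4, "D": -1.1}
        k = blomberg_k(balanced4, trait)
        # independent direct evaluation with explicit inverses
        V = np.array([[1.0, 0.7, 0.0, 0.0],
                      [0.7, 1.0, 0.0, 0.0],
                      [0.0, 0.0, 1.0, 0.5],
                      [0.0, 0.0, 0.5, 1.0]])
        y = np.array([1.2, 0.9, -0.4, -1.1])
        Vi = np.linalg.inv(V)
        one = np.ones(4)
        a = (one @ Vi @ y) / (one @ Vi @ one)
        mse0 = (y - a) @ (y - a) / 3
        mse = (y - a) @ Vi @ (y - a) / 3
        expected = (np.trace(V) - 4 / (one @ Vi @ one)) / 3
        assert k == pytest.approx((mse0 / mse) / expected, abs=1e-10)

    def test_bm_centers_near_one(self, tree32):
        ks = [blomberg_k(tree32, sim.simulate_traits_bm(tree32, 1.0, 0.0,
                                                        1.0, seed=r))
              for r in range(300)]
        assert 0.9 <= np.mean(ks) <= 1.1

    def test_iid_traits_give_low_k(self, tree32):
        ks = [blomberg_k(tree32, sim.simulate_traits_bm(tree32, 1.0, 0.0,
                                                        0.0, seed=r))
              for r in range(300)]
        assert np.mean(ks) < 0.5

    def test_constant_trait_rejected(self, tree8):
        with pytest.raises(ValueError, match="constant"):
            blomberg_k(tree8, {t: 1.0 for t in tip_labels(tree8)})


class TestPermutationTest:
    def test_p_bounds_and_determinism(self, tree8):
        trait = sim.simulate_traits_bm(tree8, 1.0, 0.0, 1.0, seed=1)
        k1, p1 = signal_permutation_test(tree8, trait, n_perm=199, seed=42)
        k2, p2 = signal_permutation_test(tree8, trait, n_perm=199, seed=42)
        assert (k1, p1) == (k2, p2)
        assert 1.0 / 200.0 <= p1 <= 1.0

    def test_type_one_error_calibrated(self, tree32):
        # under tip-label exchange the test should reject ~5% of the time
        rej = 0
        n_rep = 400
        for r in range(n_rep):
            trait = sim.simulate_traits_bm(tree32, 1.0, 0.0, 0.0, seed=r)
            _, p = signal_permutation_test(tree32, trait, n_perm=199, seed=r)
            rej += p <= 0.05
        assert 0.02 <= rej / n_rep <= 0.08

    def test_minimum_permutations_enforced(self, tree8):
        trait = sim.simulate_traits_bm(tree8, 1.0, 0.0, 1.0, seed=1)
        with pytest.raises(ValueError):
            signal_permutation_test(tree8, trait, n_perm=50)


class TestPagelLambda:
    def test_loglik_maximal_at_estimate(self, tree16):
        trait = sim.simulate_traits_bm(tree16, 1.0, 0.0, 0.7, seed=3)
        model = PagelLambda(tree16, trait)
        res = model.fit()
        assert res.loglik >= model.loglik(0.0) - 1e-9
        assert res.loglik >= model.loglik(1.0) - 1e-9
        assert 0.0 <= res.lambda_ <= 1.0
        assert 0.0 < res.lrt_pvalue <= 1.0

    def test_strong_signal_detected(self, tree32):
        lams = [PagelLambda(tree32, sim.simulate_traits_bm(
            tree32, 1.0, 0.0, 1.0, seed=r)).fit().lambda_ for r in range(50)]
        assert np.mean(lams) > 0.85

    def test_no_signal_estimates_near_zero(self, tree32):
        fits = [PagelLambda(tree32, sim.simulate_traits_bm(
            tree32, 1.0, 0.0, 0.0, seed=r)).fit() for r in range(50)]
        assert np.median([f.lambda_ for f in fits]) <= 0.1
        # LRT rejects rarely under the null (boundary makes chi2_1 conservative)
        assert np.mean([f.lrt_pvalue <= 0.05 for f in fits]) <= 0.10


class TestAgainstRReferenceImplementations:
    def test_k_and_lambda_match_picante_and_phytools(self, tree8, tmp_path):
        """Independent oracle: the R packages the field uses for K and lambda."""
        trait = sim.simulate_traits_bm(tree8, 1.0, 0.0, 0.7, seed=3)
        k = blomberg_k(tree8, trait)
        lam = PagelLambda(tree8, trait).fit()
        write_tree(tree8, tmp_path / "t.nwk")
        labs = tip_labels(tree8)
        (tmp_path / "y.csv").write_text(
            "sp,y\n" + "\n".join(f"{l},{trait[l]!r}" for l in labs))
        script = textwrap.dedent("""
            suppressMessages({library(picante); library(phytools)})
            tree <- read.tree(commandArgs(TRUE)[1])
            d <- read.csv(commandArgs(TRUE)[2])
            y <- setNames(d$y, d$sp)[tree$tip.label]
            f <- phytools::phylosig(tree, y, method="lambda")
            cat(picante::Kcalc(y, tree), f$lambda, f$logL, sep="\\n")
        """)
        (tmp_path / "oracle.R").write_text(script)
        out = subprocess.run(
            ["Rscript", str(tmp_path / "oracle.R"), str(tmp_path / "t.nwk"),
             str(tmp_path / "y.csv")], capture_output=True, text=True,
            check=True)
        r_k, r_lam, r_ll = map(float, out.stdout.split())
        assert k == pytest.approx(r_k, abs=1e-6)
        assert lam.lambda_ == pytest.approx(r_lam, abs=1e-3)
        assert lam.loglik == pytest.approx(r_ll, abs=1e-3)


class TestPGLS:
    @staticmethod
    def _table(tree, seed=0, lam=0.0, beta=(2.0, -1.0, 0.5), sigma2=0.25):
        clim = sim.simulate_climate(len(tip_labels(tree)), seed=seed)
        table, truth = sim.simulate_trait_climate(tree, clim, beta, lam,
                                                  sigma2, seed + 1)
        return table, truth

    def test_lambda_zero_equals_statsmodels_ols(self, tree16):
        import statsmodels.api as sm
        table, _ = self._table(tree16, seed=2)
        model = PGLS.from_dataframe(table, "trait", ["pc1", "subgenus"],
                                    tree16)
        fit = model.fit(lambda_mode=0.0)
        ols = sm.OLS(model.y, model.X).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params,
                                   atol=1e-8)
        np.testing.assert_allclose(fit.bse.to_numpy(), ols.bse, atol=1e-8)
        np.testing.assert_allclose(fit.pvalues.to_numpy(), ols.pvalues,
                                   atol=1e-8)

    def test_five_taxon_worked_instance_matches_brute_force(self):
        tree = htrees.simulate_yule_tree(5, seed=9)
        labels = tip_labels(tree)
        y = np.array([1.0, -0.5, 0.3, 2.0, -1.2])
        X = np.column_stack([np.ones(5), np.array([0.2, 1.1, -0.7, 0.5, -1.5])])
        lam = 0.6
        fit = PGLS(y, X, tree, labels, ["Intercept", "x"]).fit(lambda_mode=lam)
        V, _ = phylo_covariance(tree, lam, order=labels)
        Vi = np.linalg.inv(V)
        beta = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ y
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)
        r = y - X @ beta
        s2 = (r @ Vi @ r) / 3
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ Vi @ X)))
        np.testing.assert_allclose(fit.bse.to_numpy(), se, atol=1e-10)

    def test_slope_recovery_with_phylogenetic_residuals(self):
        tree = htrees.simulate_yule_tree(64, seed=17)
        slopes = []
        for r in range(60):
            table, truth = self._table(tree, seed=100 + r, lam=0.7)
            fit = PGLS.from_dataframe(table, "trait", ["pc1", "subgenus"],
                                      tree).fit("ml")
            slopes.append(fit.params["pc1"])
        assert abs(np.mean(slopes) - (-1.0)) < 0.03

    def test_singular_design_names_columns(self, tree8):
        table, _ = self._table(tree8)
        table = table.assign(pc1_copy=table["pc1"])
        with pytest.raises(ValueError, match="singular design"):
            PGLS.from_dataframe(table, "trait", ["pc1", "pc1_copy"], tree8)

    def test_joint_prune_warns(self, tree16):
        table, _ = self._table(tree16)
        with pytest.warns(UserWarning, match="dropping species"):
            PGLS.from_dataframe(table.iloc[:-2], "trait", ["pc1"], tree16)

    def test_summary_mentions_lambda_and_r2(self, tree16):
        table, _ = self._table(tree16)
        fit = PGLS.from_dataframe(table, "trait", ["pc1"], tree16).fit("ml")
        s = fit.summary()
        assert "lambda" in s and "R^2" in s and "coef" in s


class TestCooksDistance:
    def test_matches_statsmodels_at_lambda_zero(self, tree16):
        import statsmodels.api as sm
        table, _ = TestPGLS._table(tree16, seed=4)
        model = PGLS.from_dataframe(table, "trait", ["pc1", "subgenus"],
                                    tree16)
        fit = model.fit(lambda_mode=0.0)
        ours = cooks_distance(fit).to_numpy()
        theirs = sm.OLS(model.y, model.X).fit().get_influence().cooks_distance[0]
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_planted_outlier_has_max_d(self, tree16):
        table, _ = TestPGLS._table(tree16, seed=6, sigma2=0.04)
        victim = table.index[7]
        table.loc[victim, "trait"] += 6 * 0.2  # 6 residual SDs
        fit = PGLS.from_dataframe(table, "trait", ["pc1", "subgenus"],
                                  tree16).fit(lambda_mode=0.0)
        d = fit.cooks_distance()
        assert d.idxmax() == victim
        assert d.max() > 4.0 / len(table)

    def test_zero_residual_center_point_has_zero_d(self):
        tree = htrees.simulate_yule_tree(8, seed=2)
        labels = tip_labels(tree)
        x = np.array([-3.0, -2, -1, 0, 0, 1, 2, 3])
        y = 2.0 * x
        y[3] = y[4] = 0.0  # exactly on the line at the design center
        fit = PGLS(y + np.array([0.1, -0.1, 0.05, 0, 0, -0.05, 0.1, -0.1]),
                   np.column_stack([np.ones(8), x]), tree, labels).fit(0.0)
        d = fit.cooks_distance()
        assert np.isfinite(d).all()


class TestClimatePCA:
    def test_variance_sums_to_100_and_reconstructs(self):
        clim = sim.simulate_climate(20, seed=1)
        pca = climate_pca(clim)
        assert np.sum(pca.variance_explained) == pytest.approx(100.0,
                                                               abs=1e-6)
        Z = (clim - pca.center) / pca.scale
        recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T
        np.testing.assert_allclose(recon, Z.to_numpy(), atol=1e-8)
        # components orthonormal
        L = pca.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_pc1_oriented_by_min_temperature(self):
        clim = sim.simulate_climate(30, seed=2)
        pca = climate_pca(clim)
        assert pca.loadings.loc["minT", "PC1"] > 0

    def test_two_perfectly_correlated_variables(self):
        x = np.linspace(0.0, 1.0, 10)
        df = pd.DataFrame({"a": x, "b": 3.0 * x + 1.0})
        pca = climate_pca(df, columns=["a", "b"])
        assert pca.variance_explained[0] == pytest.approx(100.0, abs=1e-8)

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="b"):
            climate_pca(df, columns=["a", "b"])


class TestSmallSampleStats:
    def test_pearson_limits(self):
        x = np.arange(10.0)
        r, p = pearson_correlation(x, x)
        assert r == pytest.approx(1.0)
        r, p = pearson_correlation(x, -2.0 * x)
        assert r == pytest.approx(-1.0)

    def test_pearson_independent_near_zero(self):
        rng = np.random.default_rng(0)
        r, p = pearson_correlation(rng.standard_normal(5000),
                                   rng.standard_normal(5000))
        assert abs(r) < 0.05

    def test_pearson_degenerate(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=6),
           st.integers(min_value=0, max_value=10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bonferroni_properties(self, pvals, extra):
        m = len(pvals) + extra
        adj = bonferroni(pvals, m=m)
        assert all(0.0 <= a <= 1.0 for a in adj)
        assert all(a >= p for a, p in zip(adj, pvals))
        if extra == 0 and m == 1:
            assert adj == pvals

    def test_bonferroni_examples(self):
        assert bonferroni([0.02], m=2) == [0.04]
        assert bonferroni([0.9], m=2) == [1.0]
        with pytest.raises(ValueError):
            bonferroni([0.5, 0.1], m=1)
        with pytest.raises(ValueError):
            bonferroni([1.5], m=2)


class TestLoess:
    def test_exact_on_linear_data(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0.0, 10.0, 30))
        y = 2.0 - 0.5 * x
        for span in (0.5, 1.0, 1.5, 3.0):
            grid, fitted = loess_smooth(x, y, span=span)
            np.testing.assert_allclose(fitted, 2.0 - 0.5 * grid, atol=1e-8)

    def test_symmetric_data_gives_symmetric_fit(self):
        x = np.linspace(-3.0, 3.0, 31)
        y = x ** 2
        grid, fitted = loess_smooth(x, y, span=1.5)
        np.testing.assert_allclose(fitted, fitted[::-1], atol=1e-6)

    def test_large_span_approaches_global_linear_fit(self):
        x = np.linspace(0.0, 1.0, 25)
        y = x ** 2
        line = np.polyval(np.polyfit(x, y, 1), x)
        devs = []
        for span in (1.5, 5.0, 50.0):
            _, fitted = loess_smooth(x, y, span=span, grid=x)
            devs.append(np.max(np.abs(fitted - line)))
        assert devs[0] >= devs[1] >= devs[2]
        assert devs[2] < 1e-3

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            loess_smooth([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], span=1.0)


def test_phylo_signal_bundles_k_and_lambda(tree8):
    trait = sim.simulate_traits_bm(tree8, 1.0, 0.0, 1.0, seed=0)
    res = phylo_signal(tree8, trait, n_perm=199, seed=1)
    assert res.k > 0 and 0 < res.p_k <= 1
    assert 0 <= res.lambda_ <= 1
    d = res.to_dict()
    assert set(d) == {"k", "p_k", "lambda", "loglik_lambda", "loglik_zero",
                      "p_lambda"}
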