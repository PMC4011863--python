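"""ML fitting of BM / lambda / OU trait models and AIC comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spadefoot as sf
from spadefoot.evomodels import EvoModelFit, ModelComparison


class TestMvnLoglik:
    def test_standard_normal_density(self):
        cov = sf.PhyloCov(["a"], np.array([[1.0]]))
        assert sf.mvn_loglik(np.array([0.0]), cov, 0.0, 1.0) == pytest.approx(
            -0.5 * math.log(2 * math.pi)
        )

    def test_star_tree_reduces_to_independent_normals(self):
        t = sf.read_newick("(a:1,b:1,c:1,d:1);")
        y = np.array([0.3, -1.2, 0.7, 2.0])
        got = sf.mvn_loglik(y, sf.phylo_covariance(t), 0.5, 2.0)
        expected = stats.norm(0.5, math.sqrt(2.0)).logpdf(y).sum()
        assert got == pytest.approx(expected, abs=1e-10)

    def test_dense_algebra_oracle(self):
        """Explicit inverse and determinant on a 10-tip instance."""
        tree = sf.sim_yule_tree(10, 30.0, seed=11)
        V = sf.phylo_covariance(tree).V
        rng = np.random.default_rng(0)
        y = rng.normal(size=10)
        mu, s2 = 0.4, 1.7
        Vs = s2 * V
        r = y - mu
        expected = -0.5 * (
            10 * math.log(2 * math.pi)
            + math.log(np.linalg.det(Vs))
            + r @ np.linalg.inv(Vs) @ r
        )
        got = sf.mvn_loglik(y, sf.phylo_covariance(tree), mu, s2)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_length_mismatch_raises(self, three_tip):
        with pytest.raises(ValueError):
            sf.mvn_loglik(np.zeros(2), sf.phylo_covariance(three_tip), 0.0, 1.0)


class TestFitBM:
    def test_star_tree_iid_reduction(self):
        T = 2.0
        t = sf.read_newick("(a:2,b:2,c:2,d:2,e:2);")
        y = np.array([1.0, 2.0, 4.0, 0.5, 3.5])
        fit = sf.fit_bm(y, t)
        assert fit.mu == pytest.approx(y.mean())
        assert fit.sigma2 == pytest.approx(y.var() / T)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 4)

    def test_grid_search_oracle(self):
        """Closed-form ML beats (and localizes to) a dense 2-D grid search."""
        tree = sf.sim_yule_tree(5, 10.0, seed=3)
        y = sf.sim_trait(tree, "BM", 2.0, mu=1.0, seed=4)
        fit = sf.fit_bm(y, tree)
        cov = sf.phylo_covariance(tree)
        mus = np.linspace(fit.mu - 2, fit.mu + 2, 81)
        s2s = np.linspace(max(1e-3, fit.sigma2 / 4), fit.sigma2 * 4, 81)
        grid = np.array(
            [[sf.mvn_loglik(y.to_numpy(), cov, m, s) for s in s2s] for m in mus]
        )
        assert fit.loglik >= grid.max() - 1e-9
        i, j = np.unravel_index(grid.argmax(), grid.shape)
        assert abs(mus[i] - fit.mu) <= mus[1] - mus[0]
        assert abs(s2s[j] - fit.sigma2) <= s2s[1] - s2s[0]

    def test_recovers_simulated_rate(self):
        """sigma^2 = 2 recovered within 20% on average over seeds (200 tips)."""
        tree = sf.sim_yule_tree(200, 100.0, seed=5)
        est = [
            sf.fit_bm(sf.sim_trait(tree, "BM", 2.0, seed=s), tree).sigma2
            for s in range(50)
        ]
        assert abs(np.mean(est) - 2.0) / 2.0 < 0.2

    def test_constant_trait_flagged_degenerate(self, yule16):
        fit = sf.fit_bm(np.full(16, 3.3), yule16)
        assert fit.degenerate
        assert fit.sigma2 == 0.0
        assert math.isinf(fit.loglik)


class TestFitLambda:
    def test_grid_oracle_1001_points(self, yule64):
        y = sf.sim_trait(tree=yule64, model="LAMBDA", sigma2=1.0, shape=0.6, seed=9)
        fit = sf.fit_lambda(y, yule64)
        cov = sf.phylo_covariance(yule64)
        from spadefoot.evomodels import _profile_fit

        grid = np.linspace(0, 1, 1001)
        lls = [_profile_fit(y.to_numpy(), sf.lambda_scale(cov, g).V)[2] for g in grid]
        assert abs(grid[int(np.argmax(lls))] - fit.shape) < 1e-3

    def test_bm_data_estimates_near_upper_bound(self, yule64):
        y = sf.sim_trait(yule64, "BM", 1.0, seed=10)
        fit = sf.fit_lambda(y, yule64)
        assert fit.shape > 0.8
        assert fit.loglik >= sf.fit_bm(y, yule64).loglik - 1e-6

    def test_iid_noise_estimates_near_zero(self, yule64):
        rng = np.random.default_rng(12)
        y = pd.Series(rng.normal(size=64), index=yule64.tips)
        assert sf.fit_lambda(y, yule64).shape < 0.1

    @pytest.mark.parametrize("seed", range(5))
    def test_nesting_loglik_dominates_bm(self, seed, yule16):
        y = sf.sim_trait(yule16, "BM", 1.5, seed=seed)
        assert sf.fit_lambda(y, yule16).loglik >= sf.fit_bm(y, yule16).loglik - 1e-6


class TestFitOU:
    def test_bm_limit_nested(self, yule64):
        y = sf.sim_trait(yule64, "BM", 1.0, seed=20)
        ou = sf.fit_ou(y, yule64, seed=1)
        bm = sf.fit_bm(y, yule64)
        assert ou.loglik >= bm.loglik - 2.0

    def test_alpha_recovery(self):
        """alpha = 5/T recovered within a factor of 2 (median over seeds)."""
        tree = sf.sim_yule_tree(200, 100.0, seed=21)
        alpha_true = 5.0 / 100.0
        est = [
            sf.fit_ou(
                sf.sim_trait(tree, "OU", 1.0, shape=alpha_true, seed=s), tree, seed=s
            ).shape
            for s in range(15)
        ]
        med = np.median(est)
        assert alpha_true / 2 < med < alpha_true * 2

    def test_deterministic_given_seed(self, yule16):
        y = sf.sim_trait(yule16, "BM", 1.0, seed=22)
        f1 = sf.fit_ou(y, yule16, seed=99)
        f2 = sf.fit_ou(y, yule16, seed=99)
        assert f1.shape == f2.shape and f1.loglik == f2.loglik


class TestModelComparison:
    def test_aic_arithmetic_and_preferred_set(self):
        """Identical loglik for BM (k=2) and LAMBDA (k=3) gives dAIC = 2,
        both preferred; min dAIC is exactly 0."""
        fits = {
            "BM": EvoModelFit("BM", 0, 1, None, -10.0, 2, 16),
            "LAMBDA": EvoModelFit("LAMBDA", 0, 1, 0.5, -10.0, 3, 16),
            "OU": EvoModelFit("OU", 0, 1, 0.1, -14.0, 3, 16),
        }
        cmp_ = ModelComparison(fits)
        assert min(cmp_.delta_aic.values()) == 0.0
        assert cmp_.delta_aic["LAMBDA"] == pytest.approx(2.0)
        assert set(cmp_.preferred) == {"BM", "LAMBDA"}
        assert cmp_.delta_aic["OU"] == pytest.approx(10.0)

    def test_strong_ou_data_prefers_ou(self, yule64):
        """At a pull of 5/T the OU covariance is distinct from every
        lambda-scaled Brownian matrix, so OU alone should win the AIC race
        in most replicates.  (At much stronger pulls tips become iid and OU
        ties with lambda = 0, so this is the informative regime.)"""
        wins = 0
        for s in range(5):
            y = sf.sim_trait(yule64, "OU", 1.0, shape=5.0 / 150.0, seed=100 + s)
            cmp_ = sf.model_table(y, yule64, seed=s)
            wins += set(cmp_.preferred) == {"OU"}
        assert wins >= 4

    def test_aic_identity_exact(self, yule16):
        y = sf.sim_trait(yule16, "BM", 1.0, seed=30)
        for f in sf.model_table(y, yule16, seed=0).fits.values():
            assert f.aic == -2 * f.loglik + 2 * f.n_params


class TestTipOrderInvariance:
    def test_fits_invariant_to_tip_permutation(self):
        t1 = sf.read_newick("((a:1,b:1):1,(c:1.5,d:1.5):0.5);")
        t2 = sf.read_newick("((d:1.5,c:1.5):0.5,(b:1,a:1):1);")
        y = pd.Series({"a": 0.2, "b": 1.1, "c": -0.4, "d": 2.3})
        for fit_fn in (sf.fit_bm, sf.fit_lambda):
            f1, f2 = fit_fn(y, t1), fit_fn(y, t2)
            assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)
            assert f1.mu == pytest.approx(f2.mu, abs=1e-8)
            assert f1.sigma2 == pytest.approx(f2.sigma2, abs=1e-8)
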