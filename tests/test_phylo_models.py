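"""Likelihood oracles, fits, ancestral states and signal for the trait models."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import multivariate_normal, norm, poisson

from venomdyn.core_io import read_newick
from venomdyn.errors import NotUltrametricError
from venomdyn.phylo import (
    aic_weights,
    asr_bm,
    asr_composition,
    bm_loglik,
    eb_covariance,
    fit_bm,
    fit_eb,
    fit_ou,
    jn_loglik,
    mvn_loglik,
    ou_covariance,
    pagel_lambda,
)
from venomdyn.simulate import simulate_tree, simulate_traits
from venomdyn.phylo import ModelParams

from conftest import brute_force_covariance, random_tree


class TestBmLoglik:
    def test_two_tip_closed_form(self, two_tip_tree):
        # independent unit-variance normals around a=1 at (0, 2)
        ll = bm_loglik(np.array([0.0, 2.0]), two_tip_tree, 1.0, 1.0)
        assert ll == pytest.approx(-np.log(2 * np.pi) - 1.0, abs=1e-9)

    def test_matches_dense_mvn_on_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            t = random_tree(rng, int(rng.integers(3, 7)))
            x = rng.normal(0, 1, t.n_tips)
            s2, a = rng.uniform(0.3, 2.0), rng.normal()
            dense = multivariate_normal.logpdf(
                x, mean=a * np.ones(t.n_tips), cov=s2 * brute_force_covariance(t)
            )
            assert bm_loglik(x, t, s2, a) == pytest.approx(dense, abs=1e-6)

    def test_translation_invariance(self, three_tip_tree):
        x = np.array([0.3, -1.0, 0.5])
        base = bm_loglik(x, three_tip_tree, 0.7, 0.2)
        shifted = bm_loglik(x + 5.5, three_tip_tree, 0.7, 0.2 + 5.5)
        assert shifted == pytest.approx(base, abs=1e-10)

    def test_nonpositive_rate(self, three_tip_tree):
        with pytest.warns(UserWarning):
            assert bm_loglik(np.zeros(3), three_tip_tree, 0.0, 0.0) == -np.inf


class TestFitBm:
    def test_two_tip_star_closed_form(self, two_tip_tree):
        # GLS mean 1, ML variance ((1)^2+(1)^2)/2 / depth 1 = 1
        fit = fit_bm(np.array([0.0, 2.0, 1.0]), read_newick("(A:1,B:1,C:1);"))
        assert fit.params.root == pytest.approx(1.0)

    def test_star_tree_reduces_to_ols(self):
        t = read_newick("(A:2,B:2,C:2,D:2,E:2);")
        x = np.array([0.1, 1.4, -0.7, 2.2, 0.5])
        fit = fit_bm(x, t)
        assert fit.params.root == pytest.approx(x.mean())
        assert fit.params.sigma2 == pytest.approx(x.var() / 2.0)

    def test_constant_trait_degenerate(self, three_tip_tree):
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_bm(np.ones(3), three_tip_tree)
        assert fit.degenerate

    def test_rate_recovery_bias(self):
        # relative bias of the ML rate within ~10% at n=128
        rng = np.random.default_rng(5)
        t = simulate_tree(128, seed=9)
        est = []
        for rep in range(60):
            x = simulate_traits(t, ModelParams("BM", sigma2=2.0, root=0.0), seed=1000 + rep)
            est.append(fit_bm(x, t).params.sigma2)
        assert np.mean(est) == pytest.approx(2.0, rel=0.10)


class TestOuEb:
    def test_ou_small_alpha_limits_to_bm(self, six_tip_tree):
        x = np.array([0.5, -0.2, 3.1, 2.7, -1.0, -1.3])
        V = ou_covariance(six_tip_tree, 1.3, 1e-8)
        ll_ou = mvn_loglik(x, 0.4 * np.ones(6), V)
        ll_bm = bm_loglik(x, six_tip_tree, 1.3, 0.4)
        assert ll_ou == pytest.approx(ll_bm, abs=1e-4)

    def test_ou_covariance_hand_computed(self, three_tip_tree):
        s2, al = 1.0, 0.5
        V = ou_covariance(three_tip_tree, s2, al)
        T = 2.0
        expected_ab = s2 / (2 * al) * np.exp(-2 * al * (T - 1)) * (1 - np.exp(-2 * al * 1))
        expected_diag = s2 / (2 * al) * (1 - np.exp(-2 * al * T))
        assert V[0, 1] == pytest.approx(expected_ab, abs=1e-12)
        assert V[0, 0] == pytest.approx(expected_diag, abs=1e-12)

    def test_ou_requires_ultrametric(self):
        t = read_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(NotUltrametricError):
            fit_ou(np.array([0.0, 1.0, 2.0]), t)

    def test_ou_alpha_recovery_strong_pull(self):
        # alpha T = 5: the median estimate stays within a factor of 2
        est = []
        for rep in range(30):
            t = simulate_tree(48, seed=300 + rep)
            x = simulate_traits(
                t, ModelParams("OU", sigma2=1.0, alpha=5.0, theta=0.0, root=0.0),
                seed=400 + rep,
            )
            est.append(fit_ou(x, t).params.alpha)
        med = np.median(est)
        assert 2.5 <= med <= 10.0

    def test_eb_covariance_hand_computed(self, three_tip_tree):
        V = eb_covariance(three_tip_tree, 1.0, -1.0)
        assert V[0, 1] == pytest.approx((np.exp(-1.0) - 1) / -1.0, abs=1e-12)
        assert V[0, 0] == pytest.approx((np.exp(-2.0) - 1) / -1.0, abs=1e-12)

    def test_eb_r_zero_equals_bm(self, six_tip_tree):
        x = np.array([0.5, -0.2, 3.1, 2.7, -1.0, -1.3])
        V = eb_covariance(six_tip_tree, 0.9, 0.0)
        assert mvn_loglik(x, 0.1 * np.ones(6), V) == pytest.approx(
            bm_loglik(x, six_tip_tree, 0.9, 0.1), abs=1e-9
        )

    def test_eb_favoured_on_early_burst_data(self):
        # at r = -2/T the early burst model carries more support than BM on
        # average (the per-replicate likelihood gain must clear the one-
        # parameter AIC penalty, so mean weight is the robust summary)
        w_eb, w_bm = [], []
        reps = 15
        for rep in range(reps):
            t = simulate_tree(64, seed=500 + rep)
            x = simulate_traits(
                t, ModelParams("EB", sigma2=3.0, r=-2.0, root=0.0), seed=600 + rep
            )
            fits = aic_weights([fit_bm(x, t), fit_ou(x, t), fit_eb(x, t)])
            w_bm.append(max(fits[0].weight, fits[1].weight))
            w_eb.append(fits[2].weight)
        assert np.mean(w_eb) > np.mean(w_bm)


class TestJumpNormal:
    def test_lambda_zero_equals_bm(self, six_tip_tree):
        x = np.array([0.5, -0.2, 3.1, 2.7, -1.0, -1.3])
        assert jn_loglik(x, six_tip_tree, 0.9, 0.0, 0.0, 0.1) == pytest.approx(
            bm_loglik(x, six_tip_tree, 0.9, 0.1), abs=1e-8
        )

    def test_two_tip_quadrature_oracle(self):
        t = read_newick("(A:0.5,B:0.5);")
        s2, lam, dv, a = 0.7, 1.3, 2.0, 0.2
        xs = [0.4, -1.1]

        def incr(d, bl):
            return sum(
                poisson.pmf(k, lam * bl) * norm.pdf(d, 0, np.sqrt(s2 * bl + k * dv))
                for k in range(25)
            )

        oracle = np.log(incr(xs[0] - a, 0.5) * incr(xs[1] - a, 0.5))
        assert jn_loglik(xs, t, s2, lam, dv, a) == pytest.approx(oracle, abs=1e-6)

    def test_three_tip_jump_sum_oracle(self):
        # exact enumeration of per-branch jump counts, marginalizing the
        # internal node analytically
        t = read_newick("((A:0.6,B:0.6):0.4,C:1.0);")
        s2, lam, dv, a = 0.7, 0.9, 2.0, 0.2
        xs = [0.4, -1.1, 2.3]
        K = 22
        pair = 0.0
        for k0 in range(K):
            p0 = poisson.pmf(k0, lam * 0.4)
            for kA in range(K):
                pA = poisson.pmf(kA, lam * 0.6)
                for kB in range(K):
                    pB = poisson.pmf(kB, lam * 0.6)
                    off = s2 * 0.4 + k0 * dv
                    cov = [[s2 + (k0 + kA) * dv, off], [off, s2 + (k0 + kB) * dv]]
                    pair += p0 * pA * pB * multivariate_normal.pdf(
                        xs[:2], mean=[a, a], cov=cov
                    )
        single = sum(
            poisson.pmf(k, lam) * norm.pdf(xs[2], a, np.sqrt(s2 + k * dv))
            for k in range(K)
        )
        oracle = np.log(pair * single)
        assert jn_loglik(xs, t, s2, lam, dv, a) == pytest.approx(oracle, abs=1e-6)


class TestAicWeights:
    def _fit(self, loglik, k):
        from venomdyn.phylo.fit import ModelFit

        return ModelFit(ModelParams("BM", sigma2=1, root=0), loglik, k)

    def test_single_model_weight_one(self):
        (f,) = aic_weights([self._fit(-10.0, 2)])
        assert f.weight == pytest.approx(1.0)

    def test_delta_two_closed_form(self):
        f1, f2 = aic_weights([self._fit(-10.0, 2), self._fit(-10.0, 3)])
        assert f1.weight == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-4)
        assert f2.weight == pytest.approx(0.2689, abs=1e-4)

    def test_invariant_to_loglik_shift(self):
        a = aic_weights([self._fit(-10.0, 2), self._fit(-12.0, 3)])
        b = aic_weights([self._fit(-110.0, 2), self._fit(-112.0, 3)])
        assert a[0].weight == pytest.approx(b[0].weight, abs=1e-12)

    def test_weights_normalize(self):
        fits = aic_weights([self._fit(-10 - i, 2 + i) for i in range(4)])
        assert sum(f.weight for f in fits) == pytest.approx(1.0, abs=1e-9)


class TestAncestralStates:
    def test_symmetric_two_tip_root(self, two_tip_tree):
        states = asr_bm(np.array([0.0, 2.0]), two_tip_tree)
        assert states.root_estimate == pytest.approx(1.0)

    def test_inverse_branch_length_weighting(self):
        t = read_newick("(A:1,B:3);")
        states = asr_bm(np.array([0.0, 4.0]), t)
        assert states.root_estimate == pytest.approx(1.0)

    def test_matches_dense_gls_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            t = random_tree(rng, int(rng.integers(4, 11)))
            x = rng.normal(0, 1, t.n_tips)
            states = asr_bm(x, t, sigma2=1.0)
            C = brute_force_covariance(t)
            Cinv = np.linalg.inv(C)
            one = np.ones(t.n_tips)
            a = (one @ Cinv @ x) / (one @ Cinv @ one)
            for nd in states.estimates.index:
                cov_nt = np.array([t.mrca_depth(nd, tip) for tip in range(t.n_tips)])
                pred = a + cov_nt @ Cinv @ (x - a)
                assert states.estimates[nd] == pytest.approx(pred, abs=1e-8)

    def test_estimates_within_tip_range(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            t = random_tree(rng, 8)
            x = rng.normal(0, 2, 8)
            states = asr_bm(x, t)
            assert states.estimates.min() >= x.min() - 1e-9
            assert states.estimates.max() <= x.max() + 1e-9


class TestAsrComposition:
    def test_identical_tips_constant_everywhere(self, two_tip_tree):
        import pandas as pd

        comp = pd.DataFrame(
            {"NaTx": [0.7, 0.7], "KTx3": [0.3, 0.3]}, index=["A", "B"]
        )
        nodes = asr_composition(comp, two_tip_tree)
        assert nodes["NaTx"].iloc[0] == pytest.approx(0.7)

    def test_opposite_tips_give_midpoint_root(self, two_tip_tree):
        import pandas as pd

        comp = pd.DataFrame(
            {"NaTx": [1.0, 0.0], "KTx3": [0.0, 1.0]}, index=["A", "B"]
        )
        nodes = asr_composition(comp, two_tip_tree)
        assert nodes["NaTx"].iloc[0] == pytest.approx(0.5)

    def test_node_fractions_sum_to_one(self):
        import pandas as pd

        rng = np.random.default_rng(13)
        t = simulate_tree(12, seed=31)
        comp = pd.DataFrame(
            rng.dirichlet(np.ones(4), size=12),
            index=t.tip_labels,
            columns=["NaTx", "KTx3", "Actinoporin", "NEP3"],
        )
        nodes = asr_composition(comp, t)
        np.testing.assert_allclose(nodes.sum(axis=1), 1.0, atol=1e-9)


class TestPagelLambda:
    def test_lambda_one_is_bm_likelihood(self):
        t = simulate_tree(16, seed=3)
        x = simulate_traits(t, ModelParams("BM", sigma2=1.0, root=0.0), seed=4)
        C = t.shared_path_matrix()
        fit = fit_bm(x, t)
        ll_bm = fit.loglik
        ll_l1 = mvn_loglik(
            x, fit.params.root * np.ones(16), fit.params.sigma2 * C
        )
        assert ll_l1 == pytest.approx(ll_bm, abs=1e-8)

    def test_signal_detected_under_bm(self):
        lams = []
        for rep in range(25):
            t = simulate_tree(64, seed=700 + rep)
            x = simulate_traits(t, ModelParams("BM", sigma2=1.0, root=0.0), seed=800 + rep)
            lams.append(pagel_lambda(x, t)[0])
        assert np.median(lams) >= 0.8

    def test_no_signal_for_iid_data(self):
        rng = np.random.default_rng(17)
        low = 0
        reps = 25
        for rep in range(reps):
            t = simulate_tree(64, seed=900 + rep)
            x = rng.normal(0, 1, 64)
            if pagel_lambda(x, t)[0] <= 0.1:
                low += 1
        assert low >= 0.9 * reps
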