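import numpy as np
import pytest

import crossgs as cg
from crossgs import mcmc
from crossgs.mcmc import Hyperparams, InvalidInputError, MCMCConfig


@pytest.fixture
def rng():
    return np.random.default_rng(11)


def ridge_solution(Xc, yc, lam):
    """Direct mixed-model-equation solve: (X'X + lam I) b = X'y."""
    k = Xc.shape[1]
    return np.linalg.solve(Xc.T @ Xc + lam * np.eye(k), Xc.T @ yc)


class TestHyperparameters:
    def test_scale_from_expectation(self):
        # S^2 = E (nu - 2) / nu: engineered so E(sigma_alpha^2) = 1
        k, e2pq, pi0 = 50, 0.4, 0.9
        p = np.full(k, 0.5 - np.sqrt(0.25 - e2pq / 2))
        cfg = MCMCConfig(pi0_alpha=pi0)
        hp = mcmc.derive_hyperparameters(
            v_a=k * (1 - pi0) * e2pq, v_d=0.0, v_e=1.0, h=0.0,
            snp_freqs=p, delta=None, cfg=cfg, model_kind="additive")
        assert np.isclose(hp.S2_alpha, 0.5)
        assert np.isclose(hp.S2_e, 0.5)

    def test_zero_heterosis_gives_zero_eta(self, rng):
        p = rng.uniform(0.2, 0.8, 100)
        hp = mcmc.derive_hyperparameters(
            0.7, 0.3, 1.0, 0.0, p, delta=rng.normal(0, 0.2, 100),
            cfg=MCMCConfig(), model_kind="dominance")
        assert hp.eta == 0.0
        assert hp.S2_d > 0

    def test_degenerate_dominance_slab_falls_back(self, rng):
        # V_D = 0 and H = 0 make Eq-style sigma_d^2 vanish; the fallback
        # keeps the slab at the additive per-effect scale
        p = rng.uniform(0.2, 0.8, 100)
        cfg = MCMCConfig()
        hp = mcmc.derive_hyperparameters(
            1.0, 0.0, 1.0, 0.0, p, delta=np.zeros(100), cfg=cfg,
            model_kind="dominance")
        e2pq = np.mean(2 * p * (1 - p))
        expect = 1.0 / (100 * 0.1 * e2pq)
        assert np.isclose(hp.S2_d, expect * 0.5)

    def test_large_eta_clamp_warns(self, rng):
        p = rng.uniform(0.4, 0.6, 50)
        with pytest.warns(RuntimeWarning):
            mcmc.derive_hyperparameters(
                0.5, 1e-4, 1.0, 5.0, p, delta=np.full(50, 0.01),
                cfg=MCMCConfig(), model_kind="dominance")

    def test_config_validation(self):
        with pytest.raises(InvalidInputError):
            MCMCConfig(chain_length=100, burn_in=200)
        with pytest.raises(InvalidInputError):
            MCMCConfig(pi0_d=1.0)


class TestAdditiveModel:
    def test_constant_phenotype_gives_null_effects(self, rng):
        X = rng.integers(0, 3, (80, 30))
        y = np.full(80, 3.7)
        hp = Hyperparams(S2_e=0.5, S2_alpha=0.01)
        fit = mcmc.fit_additive(X, y, hp, MCMCConfig(chain_length=2000,
                                                     burn_in=500), seed=rng)
        assert np.abs(fit.effects["alpha"]).max() < 0.02
        assert np.isclose(fit.mu, 3.7, atol=0.05)

    def test_non_finite_phenotypes_rejected(self, rng):
        X = rng.integers(0, 3, (10, 4))
        y = np.full(10, np.nan)
        hp = Hyperparams(S2_e=0.5, S2_alpha=0.01)
        with pytest.raises(InvalidInputError):
            mcmc.fit_additive(X, y, hp, MCMCConfig())

    def test_matches_ridge_with_pi_zero_and_fixed_variances(self, rng):
        # oracle: with Pi = 0 and variances fixed, the posterior mean is
        # the BLUP/ridge solution of the mixed-model equations
        n, k = 50, 20
        X = rng.integers(0, 3, (n, k)).astype(float)
        beta = rng.normal(0, 0.5, k)
        y = X @ beta + rng.normal(0, 1.0, n)
        var_a, var_e = 0.25, 1.0
        cfg = MCMCConfig(pi_fixed=0.0, update_variances=False,
                         chain_length=11000, burn_in=1000)
        hp = Hyperparams(S2_e=var_e * 0.5, S2_alpha=var_a * 0.5)
        fit = mcmc.fit_additive(X, y, hp, cfg, seed=rng)
        Xc = X - X.mean(0)
        expected = ridge_solution(Xc, y - y.mean(), var_e / var_a)
        assert np.max(np.abs(fit.effects["alpha"] - expected)) < 0.05
        assert np.corrcoef(fit.effects["alpha"], expected)[0, 1] > 0.999

    def test_detects_single_strong_qtl(self, rng):
        # one SNP explaining half the variance on n = 500 records
        n, k = 500, 60
        X = rng.binomial(2, 0.5, (n, k)).astype(float)
        beta = np.zeros(k)
        beta[17] = 1.0                      # var = 2pq = 0.5 = V_E
        y = X @ beta + rng.normal(0, np.sqrt(0.5), n)
        cfg = MCMCConfig(chain_length=4000, burn_in=1000)
        hp = mcmc.derive_hyperparameters(
            0.5, 0.0, 0.5, 0.0, np.full(k, 0.5), None, cfg, "additive")
        fit = mcmc.fit_additive(X, y, hp, cfg, seed=rng)
        assert fit.inclusion["alpha"][17] > 0.9
        assert np.isclose(fit.effects["alpha"][17], 1.0, atol=0.15)

    def test_residual_variance_recovered_on_null_data(self, rng):
        # with every marker excluded (Pi = 1), sigma_e^2 tracks Var(y)
        n, ve = 400, 0.8
        X = rng.integers(0, 3, (n, 20))
        y = rng.normal(0, np.sqrt(ve), n)
        cfg = MCMCConfig(pi_fixed=1.0, chain_length=3000, burn_in=500)
        hp = Hyperparams(S2_e=ve * 0.5, S2_alpha=0.01)
        fit = mcmc.fit_additive(X, y, hp, cfg, seed=rng)
        assert np.isclose(fit.sigma_e2, y.var(), rtol=0.1)

    def test_forced_pi_extremes_count(self, rng):
        X = rng.integers(0, 3, (40, 15))
        y = rng.normal(0, 1, 40)
        hp = Hyperparams(S2_e=0.5, S2_alpha=0.01)
        cfg1 = MCMCConfig(pi_fixed=1.0, chain_length=500, burn_in=100)
        f1 = mcmc.fit_additive(X, y, hp, cfg1, seed=rng)
        assert cg.count_nonzero_effects(f1)["alpha"] == 0
        cfg0 = MCMCConfig(pi_fixed=0.0, chain_length=500, burn_in=100)
        f0 = mcmc.fit_additive(X, y, hp, cfg0, seed=rng)
        assert cg.count_nonzero_effects(f0)["alpha"] == 15

    def test_monomorphic_columns_pinned_to_zero(self, rng):
        X = rng.integers(0, 3, (60, 10)).astype(float)
        X[:, 4] = 2.0
        y = rng.normal(0, 1, 60)
        hp = Hyperparams(S2_e=0.5, S2_alpha=0.05)
        fit = mcmc.fit_additive(X, y, hp,
                                MCMCConfig(chain_length=800, burn_in=200),
                                seed=rng)
        assert fit.effects["alpha"][4] == 0.0
        assert fit.inclusion["alpha"][4] == 0.0

    def test_column_permutation_equivariance(self, rng):
        # permuting SNP columns permutes the posterior summaries
        n, k = 60, 10
        X = rng.binomial(2, 0.4, (n, k)).astype(float)
        y = X[:, 3] * 0.8 + rng.normal(0, 0.6, n)
        hp = Hyperparams(S2_e=0.3, S2_alpha=0.05)
        cfg = MCMCConfig(chain_length=11000, burn_in=1000)
        perm = rng.permutation(k)
        f1 = mcmc.fit_additive(X, y, hp, cfg, seed=1)
        f2 = mcmc.fit_additive(X[:, perm], y, hp, cfg, seed=2)
        assert np.max(np.abs(f2.effects["alpha"]
                             - f1.effects["alpha"][perm])) < 0.06

    def test_chain_doubling_stability(self, rng):
        # doubling the chain changes posterior-mean effects by < 2% RMS
        n, k = 300, 150
        X = rng.binomial(2, 0.4, (n, k)).astype(float)
        beta = np.where(rng.random(k) < 0.1, rng.normal(0, 0.4, k), 0.0)
        y = X @ beta + rng.normal(0, 1, n)
        hp = mcmc.derive_hyperparameters(
            float(np.var(X @ beta)), 0.0, 1.0, 0.0, X.mean(0) / 2, None,
            MCMCConfig(), "additive")
        f1 = mcmc.fit_additive(X, y, hp, MCMCConfig(), seed=3)
        f2 = mcmc.fit_additive(
            X, y, hp, MCMCConfig(chain_length=22000, burn_in=2000), seed=4)
        scale = np.sqrt(np.mean(f1.effects["alpha"] ** 2))
        rms = np.sqrt(np.mean((f1.effects["alpha"]
                               - f2.effects["alpha"]) ** 2))
        assert rms < 0.02 * scale


class TestDominanceModel:
    def test_joint_ridge_oracle(self, rng):
        # Pi -> 0, fixed variances, mu_d fixed at 0: posterior mean equals
        # the joint ridge solution for [a; d]
        n, k = 50, 8
        X = rng.binomial(2, 0.5, (n, k)).astype(float)
        W = (X == 1).astype(float)
        a = rng.normal(0, 0.5, k)
        d = rng.normal(0, 0.5, k)
        y = X @ a + W @ d + rng.normal(0, 1, n)
        va, vd, ve = 0.3, 0.3, 1.0
        cfg = MCMCConfig(pi_fixed=0.0, update_variances=False,
                         mu_d_fixed=0.0, chain_length=11000, burn_in=1000)
        hp = Hyperparams(S2_e=0.5, S2_a=va * 0.5, S2_d=vd * 0.5, eta=0.0)
        fit = mcmc.fit_dominance(X, W, y, hp, cfg, seed=rng)
        Xc, Wc = X - X.mean(0), W - W.mean(0)
        Z = np.hstack([Xc, Wc])
        lam = np.diag([ve / va] * k + [ve / vd] * k)
        expected = np.linalg.solve(Z.T @ Z + lam, Z.T @ (y - y.mean()))
        got = np.concatenate([fit.effects["a"], fit.effects["d"]])
        assert np.max(np.abs(got - expected)) < 0.07
        assert np.corrcoef(got, expected)[0, 1] > 0.995

    def test_null_dominance_data_collapses_d_class(self, rng):
        # purely additive records: few nonzero d effects are fitted
        n, k = 400, 100
        X = rng.binomial(2, 0.5, (n, k)).astype(float)
        W = (X == 1).astype(float)
        beta = np.where(rng.random(k) < 0.1, rng.normal(0, 0.5, k), 0.0)
        y = X @ beta + rng.normal(0, 1, n)
        cfg = MCMCConfig(chain_length=4000, burn_in=1000)
        hp = mcmc.derive_hyperparameters(
            float(np.var(X @ beta)), 0.0, 1.0, 0.0, np.full(k, 0.5),
            np.zeros(k), cfg, "dominance")
        fit = mcmc.fit_dominance(X, W, y, hp, cfg, seed=rng)
        counts = cg.count_nonzero_effects(fit)
        assert counts["d"] < 0.15 * k
        assert counts["d"] < counts["a"]

    def test_recovers_overdominant_qtl_and_mu_d_sign(self, rng):
        # a = 0, d large at one locus: its d effect is included and the
        # slab mean mu_d picks up the sign of d
        n, k = 500, 50
        X = rng.binomial(2, 0.5, (n, k)).astype(float)
        W = (X == 1).astype(float)
        d_true = 1.2
        y = W[:, 31] * d_true + rng.normal(0, 0.7, n)
        cfg = MCMCConfig(chain_length=4000, burn_in=1000)
        hp = mcmc.derive_hyperparameters(
            0.05, float(np.var(W[:, 31] * d_true)) * 4, 0.5, 0.3,
            np.full(k, 0.5), np.full(k, 0.3), cfg, "dominance")
        fit = mcmc.fit_dominance(X, W, y, hp, cfg, seed=rng)
        assert fit.inclusion["d"][31] > 0.9
        assert fit.mu_d > 0

    def test_sum_all_k_mode_shrinks_mu_d_harder(self, rng):
        # on null data the all-k convention divides the prior pull by
        # k + phi instead of n_in + phi, dragging mu_d towards zero
        n, k = 100, 100
        X = rng.binomial(2, 0.5, (n, k)).astype(float)
        W = (X == 1).astype(float)
        y = rng.normal(0, 1, n)
        hp = Hyperparams(S2_e=0.5, S2_a=0.02, S2_d=0.02, eta=0.3)
        base = dict(chain_length=1500, burn_in=500)
        f_all = mcmc.fit_dominance(
            X, W, y, hp, MCMCConfig(mu_d_sum_all=True, **base), seed=1)
        f_inc = mcmc.fit_dominance(
            X, W, y, hp, MCMCConfig(mu_d_sum_all=False, **base), seed=1)
        assert abs(f_all.mu_d) < 0.6 * abs(f_inc.mu_d)
        assert abs(f_all.mu_d) < 0.1


class TestBSAM:
    def test_rejects_unphased_dosages(self, rng):
        XA = rng.integers(0, 3, (20, 5))     # 0/1/2: not allele dosages
        XB = rng.integers(0, 2, (20, 5))
        hp = Hyperparams(S2_e=0.5, S2_alpha_A=0.01, S2_alpha_B=0.01)
        with pytest.raises(InvalidInputError):
            mcmc.fit_bsam(XA, XB, rng.normal(size=20), hp, MCMCConfig())

    def test_constant_phenotype_gives_null_effects(self, rng):
        XA = rng.integers(0, 2, (60, 10))
        XB = rng.integers(0, 2, (60, 10))
        y = np.zeros(60)
        hp = Hyperparams(S2_e=0.5, S2_alpha_A=0.01, S2_alpha_B=0.01)
        fit = mcmc.fit_bsam(XA, XB, y, hp,
                            MCMCConfig(chain_length=1500, burn_in=500),
                            seed=rng)
        assert np.abs(fit.effects["alpha_A"]).max() < 0.02
        assert np.abs(fit.effects["alpha_B"]).max() < 0.02

    def test_fixed_origin_column_is_pinned(self, rng):
        # SNP fixed in breed B: its B-origin column is constant and the
        # effect stays exactly zero
        XA = rng.integers(0, 2, (80, 6)).astype(float)
        XB = rng.integers(0, 2, (80, 6)).astype(float)
        XB[:, 2] = 1.0
        y = XA @ rng.normal(0, 0.5, 6) + rng.normal(0, 1, 80)
        hp = Hyperparams(S2_e=0.5, S2_alpha_A=0.05, S2_alpha_B=0.05)
        fit = mcmc.fit_bsam(XA, XB, y, hp,
                            MCMCConfig(chain_length=1500, burn_in=500),
                            seed=rng)
        assert fit.effects["alpha_B"][2] == 0.0

    def test_symmetric_origins_give_symmetric_estimates(self, rng):
        # identical effect simulated for both origins, strong signal
        n, k = 1500, 4
        XA = rng.integers(0, 2, (n, k)).astype(float)
        XB = rng.integers(0, 2, (n, k)).astype(float)
        beta = np.array([1.0, -0.8, 0.6, 0.0])
        y = (XA + XB) @ beta + rng.normal(0, 0.5, n)
        cfg = MCMCConfig(pi_fixed=0.0, chain_length=6000, burn_in=1000)
        hp = Hyperparams(S2_e=0.15, S2_alpha_A=0.3, S2_alpha_B=0.3)
        fit = mcmc.fit_bsam(XA, XB, y, hp, cfg, seed=rng)
        np.testing.assert_allclose(fit.effects["alpha_A"],
                                   fit.effects["alpha_B"], atol=0.1)
        np.testing.assert_allclose(fit.effects["alpha_A"], beta, atol=0.1)


class TestBSAMMisfitIdentity:
    @pytest.mark.parametrize("pa,pb,a,d", [
        (0.7, 0.3, 0.5, 0.8), (0.4, 0.9, 0.3, -0.6), (0.5, 0.2, 0.0, 1.0),
    ])
    def test_genotype_mean_deviates(self, pa, pb, a, d):
        # best additive-in-origin-alleles fit to the four genotype means
        # leaves deviates eps01 - eps00 = 2 p^A d and
        # eps10 - eps00 = 2 p^B d (weighted least squares oracle)
        g = np.array([0.0, a + d, a + d, 2 * a])          # 00, 01, 10, 11
        design = np.array([[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]],
                          float)                           # [mu, xA, xB]
        w = np.array([(1 - pa) * (1 - pb), (1 - pa) * pb,
                      pa * (1 - pb), pa * pb])
        Wm = np.diag(w)
        coef = np.linalg.solve(design.T @ Wm @ design, design.T @ Wm @ g)
        eps = g - design @ coef
        assert np.isclose(eps[1] - eps[0], 2 * pa * d, atol=1e-10)
        assert np.isclose(eps[2] - eps[0], 2 * pb * d, atol=1e-10)
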