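import math

import numpy as np
import pytest
from scipy.special import expit, logsumexp

from cogmix import fmm, synthetic as syn
from cogmix.fmm import (
    FMMParams,
    FMMSpec,
    align_alpha,
    e_step,
    fit_fa,
    fit_fmm,
    fit_lca,
    fmm_loglik,
    information_criteria,
    m_step_multinomial,
    model_ladder,
    odds_ratio_from_coefficient,
)


def toy_params(K=2, J=4, lam=None, tau=None, alpha=None, pi=None):
    lam = np.full((J, 1), 0.8) if lam is None else np.asarray(lam, float).reshape(J, 1)
    tau = np.zeros(J) if tau is None else np.asarray(tau, float)
    alpha = np.array([[-1.0], [1.0]])[:K] if alpha is None else np.asarray(alpha, float).reshape(K, 1)
    pi = np.full(K, 1.0 / K) if pi is None else np.asarray(pi, float)
    return FMMParams(tau=tau, lam=lam, alpha=alpha, psi=np.zeros((K, 1)),
                     sigma2=np.empty(0), pi=pi)


class TestArithmetic:
    @pytest.mark.parametrize("ll, p, n, bic, aic", [
        (-100.0, 5, 100, 223.02585092994046, 210.0),
        (-50.0, 0, 10, 100.0, 100.0),
        (0.0, 1, math.e, 1.0, 2.0),
    ])
    def test_information_criteria(self, ll, p, n, bic, aic):
        got_bic, got_aic = information_criteria(ll, p, n)
        assert got_bic == pytest.approx(bic, abs=1e-9)
        assert got_aic == pytest.approx(aic, abs=1e-9)

    def test_odds_ratio_published_coefficients(self):
        orr, pct = odds_ratio_from_coefficient(-0.963)
        assert orr == pytest.approx(0.382, abs=5e-4)
        assert pct == pytest.approx(-61.8, abs=0.05)
        assert odds_ratio_from_coefficient(-0.048)[0] == pytest.approx(0.953, abs=5e-4)
        assert odds_ratio_from_coefficient(0.0) == (1.0, 0.0)


class TestLoglik:
    def test_independence_model(self):
        """K=1, lambda=0: loglik is the sum of independent Bernoulli logliks."""
        Y = np.array([[1.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
        tau = np.array([0.3, -0.2, 0.8])
        params = toy_params(K=1, J=3, lam=np.zeros(3), tau=tau, alpha=[0.0], pi=[1.0])
        spec = FMMSpec(1, 1, "FMM1", covariate_included=False)
        p = expit(tau)
        expected = np.sum(Y * np.log(p) + (1 - Y) * np.log(1 - p))
        assert fmm_loglik(Y, params, spec) == pytest.approx(expected, abs=1e-10)

    def test_matches_enumeration_oracle(self):
        """Exhaustive class-marginalization on a tiny binary instance."""
        rng = np.random.default_rng(3)
        Y = rng.integers(0, 2, size=(8, 6)).astype(float)
        params = toy_params(K=2, J=6,
                            lam=rng.uniform(-0.5, 1.0, 6),
                            tau=rng.normal(0, 0.5, 6),
                            alpha=[-1.451, 0.657], pi=[0.3, 0.7])
        spec = FMMSpec(2, 1, "FMM1", covariate_included=False)
        # oracle: direct sum over class assignments
        expected = 0.0
        for i in range(8):
            tot = 0.0
            for k, a in enumerate((-1.451, 0.657)):
                pk = expit(params.tau + params.lam[:, 0] * a)
                lik = np.prod(np.where(Y[i] == 1, pk, 1 - pk))
                tot += params.pi[k] * lik
            expected += math.log(tot)
        assert fmm_loglik(Y, params, spec) == pytest.approx(expected, abs=1e-10)

    def test_fmm2_collapses_to_fmm1_at_zero_variance(self):
        rng = np.random.default_rng(4)
        Y = rng.integers(0, 2, size=(6, 5)).astype(float)
        params = toy_params(K=2, J=5, lam=rng.uniform(0.2, 0.9, 5),
                            tau=rng.normal(size=5))
        ll1 = fmm_loglik(Y, params, FMMSpec(2, 1, "FMM1", covariate_included=False))
        params2 = FMMParams(tau=params.tau, lam=params.lam, alpha=params.alpha,
                            psi=np.full((2, 1), 1e-8), sigma2=np.empty(0),
                            pi=params.pi)
        ll2 = fmm_loglik(Y, params2, FMMSpec(2, 1, "FMM2", covariate_included=False))
        assert ll2 == pytest.approx(ll1, abs=1e-6)

    def test_negative_psi_rejected(self):
        Y = np.zeros((2, 3))
        params = toy_params(K=2, J=3)
        params.psi = np.array([[-0.1], [0.2]])
        with pytest.raises(ValueError):
            fmm_loglik(Y, params, FMMSpec(2, 1, "FMM2", covariate_included=False))


class TestEStep:
    def test_single_class_all_ones(self):
        Y = np.random.default_rng(0).integers(0, 2, (5, 4)).astype(float)
        params = toy_params(K=1, J=4, alpha=[0.0], pi=[1.0])
        resp = e_step(Y, params, FMMSpec(1, 1, covariate_included=False))
        np.testing.assert_allclose(resp, 1.0)

    def test_identical_classes_return_prior(self):
        Y = np.random.default_rng(1).integers(0, 2, (6, 4)).astype(float)
        params = toy_params(K=2, J=4, alpha=[0.0, 1e-15], pi=[0.3, 0.7])
        resp = e_step(Y, params, FMMSpec(2, 1, covariate_included=False))
        np.testing.assert_allclose(resp, np.tile([0.3, 0.7], (6, 1)), atol=1e-9)

    def test_matches_hand_bayes(self):
        """Two persons, two items, posterior computed by hand."""
        Y = np.array([[1.0, 1.0], [0.0, 0.0]])
        tau = np.array([0.0, 0.0])
        lam = np.array([1.0, 1.0])
        alpha = np.array([-1.0, 1.0])
        pi = np.array([0.4, 0.6])
        params = toy_params(K=2, J=2, lam=lam, tau=tau, alpha=alpha, pi=pi)
        resp = e_step(Y, params, FMMSpec(2, 1, covariate_included=False))
        hand = np.empty((2, 2))
        for i in range(2):
            liks = np.array([
                np.prod(np.where(Y[i] == 1, expit(tau + lam * a), 1 - expit(tau + lam * a)))
                for a in alpha
            ])
            hand[i] = pi * liks / (pi * liks).sum()
        np.testing.assert_allclose(resp, hand, atol=1e-12)


class TestMultinomialMStep:
    def test_code_independent_responsibilities_give_zero_slope(self):
        rng = np.random.default_rng(2)
        R = np.tile([0.35, 0.65], (300, 1))
        code = rng.choice([-1, 0, 1], size=300)
        g0, g1 = m_step_multinomial(R, code)
        assert abs(g1[0]) < 1e-6

    def test_recovers_published_pattern(self):
        """Responsibilities set to the exact logistic pattern are recovered."""
        code = np.repeat([-1, 0, 1], 50)
        p1 = expit(-0.048 - 0.963 * code)
        R = np.stack([p1, 1 - p1], axis=1)
        g0, g1 = m_step_multinomial(R, code)
        assert g0[0] == pytest.approx(-0.048, abs=1e-3)
        assert g1[0] == pytest.approx(-0.963, abs=1e-3)

    def test_degenerate_mass_capped_with_warning(self):
        R = np.tile([0.0, 1.0], (60, 1))
        code = np.repeat([-1, 0, 1], 20)
        with pytest.warns(UserWarning, match="capped"):
            g0, _ = m_step_multinomial(R, code)
        assert abs(g0[0]) <= 15.0 + 1e-9


class TestLCA:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(5)
        Y = rng.integers(0, 2, size=(40, 6)).astype(float)
        fit = fit_lca(Y, K=1)
        p = Y.mean(axis=0)
        p = np.clip(p, 1e-6, 1 - 1e-6)
        expected = float(np.sum(Y * np.log(p) + (1 - Y) * np.log(1 - p)))
        assert fit.loglik == pytest.approx(expected, abs=1e-6)

    def test_separable_two_point(self):
        Y = np.vstack([np.zeros((10, 5)), np.ones((10, 5))])
        fit = fit_lca(Y, K=2, seed=0)
        hard = fit.responsibilities.argmax(axis=1)
        assert len(set(hard[:10])) == 1 and len(set(hard[10:])) == 1
        assert hard[0] != hard[10]
        np.testing.assert_allclose(np.sort(fit.params.pi), [0.5, 0.5], atol=1e-6)
        assert fit.responsibilities.max() > 0.999

    def test_six_row_grid_search_oracle(self):
        """EM is at least as good as brute-force grid maximization and never
        beats the saturated pattern fit."""
        Y = np.array([[1, 1], [1, 1], [1, 0], [0, 0], [0, 1], [0, 0]], dtype=float)
        fit = fit_lca(Y, K=2, seed=1, restarts=8, tol=1e-12)
        # vectorized grid oracle over (p11, p12, p21, p22, pi1)
        g = np.linspace(0.01, 0.99, 25)
        p11, p12, p21, p22, pi1 = np.meshgrid(g, g, g, g,
                                              np.linspace(0.05, 0.95, 10),
                                              indexing="ij", sparse=True)
        best = -np.inf
        counts = {(1, 1): 2.0, (1, 0): 1.0, (0, 1): 1.0, (0, 0): 2.0}
        total = 0.0
        for (y1, y2), cnt in counts.items():
            f1 = (p11 if y1 else 1 - p11) * (p12 if y2 else 1 - p12)
            f2 = (p21 if y1 else 1 - p21) * (p22 if y2 else 1 - p22)
            total = total + cnt * np.log(pi1 * f1 + (1 - pi1) * f2)
        best = float(total.max())
        saturated = float(sum(c * math.log(c / 6.0) for c in counts.values()))
        assert fit.loglik >= best - 1e-4
        assert fit.loglik <= saturated + 1e-9


class TestFA:
    def test_loading_recovery(self):
        """One-factor binary data with lambda = 0.6 recovered within 0.1."""
        rng = np.random.default_rng(8)
        n, J = 2000, 12
        eta = rng.standard_normal(n)
        tau = rng.normal(0, 0.3, J)
        Y = (rng.uniform(size=(n, J)) < expit(tau + 0.6 * eta[:, None])).astype(float)
        fit = fit_fa(Y, F=1, seed=0)
        lam = fit.params.lam[:, 0]
        sign = np.sign(lam.mean())
        assert np.abs(sign * lam - 0.6).mean() < 0.1

    def test_determinism(self, fmm_dataset):
        f1 = fit_fa(fmm_dataset, F=1, seed=3, max_iter=40)
        f2 = fit_fa(fmm_dataset, F=1, seed=3, max_iter=40)
        assert f1.bic == f2.bic

    def test_independent_noise_shrinks_loadings(self):
        rng = np.random.default_rng(9)
        Y = rng.integers(0, 2, size=(800, 8)).astype(float)
        fit = fit_fa(Y, F=1, seed=0)
        assert np.abs(fit.params.lam).mean() < 0.35
        # FA must not look better than the independence model by BIC
        p = np.clip(Y.mean(axis=0), 1e-9, None)
        ll0 = float(np.sum(Y * np.log(p) + (1 - Y) * np.log(1 - p)))
        bic0, _ = information_criteria(ll0, Y.shape[1], Y.shape[0])
        assert fit.bic >= bic0 - 1e-6
        assert fit.loglik <= ll0 + 15.0


class TestFitFMM:
    def test_recovery_at_published_truth(self, default_truth):
        ds = syn.simulate_fmm1(2500, default_truth, seed=100)
        fit = fit_fmm(ds, FMMSpec(2, 1, "FMM1"), restarts=3, seed=0)
        aligned = align_alpha(fit.params, default_truth.loadings,
                              default_truth.thresholds, ds.schema.binary_mask)
        assert np.abs(aligned - np.array([-1.451, 0.657])).max() < 0.15
        true_prop = np.bincount(ds.true_labels) / ds.n
        np.testing.assert_allclose(fit.responsibilities.mean(axis=0), true_prop,
                                   atol=0.03)
        assert fit.params.gamma1[0] == pytest.approx(-0.963, abs=0.15)

    def test_em_monotone(self, fmm_dataset):
        fit = fit_fmm(fmm_dataset, FMMSpec(2, 1, "FMM1"), restarts=2, seed=1)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_determinism(self, fmm_dataset):
        f1 = fit_fmm(fmm_dataset, FMMSpec(2, 1, "FMM1"), restarts=2, seed=5)
        f2 = fit_fmm(fmm_dataset, FMMSpec(2, 1, "FMM1"), restarts=2, seed=5)
        assert f1.loglik == f2.loglik
        np.testing.assert_array_equal(f1.params.alpha, f2.params.alpha)

    def test_fmm2_nests_fmm1(self, fmm_dataset):
        fit1 = fit_fmm(fmm_dataset, FMMSpec(2, 1, "FMM1"), restarts=2, seed=2)
        fit2 = fit_fmm(fmm_dataset, FMMSpec(2, 1, "FMM2"), restarts=1, seed=2,
                       warm_start=fit1)
        assert fit2.loglik >= fit1.loglik - 1e-6

    def test_classes_ordered_ascending(self, fmm_dataset):
        fit = fit_fmm(fmm_dataset, FMMSpec(2, 1, "FMM1"), restarts=2, seed=3)
        assert fit.params.alpha[0, 0] < fit.params.alpha[1, 0]

    def test_relabeling_invariance(self):
        """Permuting class labels in the parameters leaves the loglik unchanged."""
        rng = np.random.default_rng(11)
        Y = rng.integers(0, 2, (30, 5)).astype(float)
        params = toy_params(K=2, J=5, lam=rng.uniform(0.2, 0.8, 5),
                            tau=rng.normal(size=5), alpha=[-0.8, 0.9],
                            pi=[0.45, 0.55])
        spec = FMMSpec(2, 1, covariate_included=False)
        ll = fmm_loglik(Y, params, spec)
        flipped = toy_params(K=2, J=5, lam=params.lam[:, 0], tau=params.tau,
                             alpha=[0.9, -0.8], pi=[0.55, 0.45])
        assert fmm_loglik(Y, flipped, spec) == pytest.approx(ll, abs=1e-10)


class TestLadder:
    def test_single_cell_grid(self, fmm_dataset):
        res = model_ladder(fmm_dataset, class_grid=(2,), factor_grid=(1,),
                           seed=0, restarts=1)
        assert res.winner.spec.n_classes == 2
        ok = res.table[res.table.converged]
        assert res.winner.bic == ok.bic.min()

    def test_selects_generating_model(self, default_truth):
        ds = syn.simulate_fmm1(1000, default_truth, seed=77)
        res = model_ladder(ds, class_grid=(1, 2, 3), factor_grid=(1,),
                           seed=0, restarts=2)
        w = res.winner
        assert (w.model, w.spec.n_classes, w.spec.n_factors) == ("FMM1", 2, 1)


class TestResponseProfiles:
    def test_loading_sign_controls_gap_direction(self):
        params = toy_params(K=2, J=3, lam=[0.0, 0.7, -0.41],
                            tau=[0.1, 0.0, 0.2], alpha=[-1.451, 0.657])
        prof = fmm.expected_response_profiles(params)[:, :3]
        assert prof[0, 0] == pytest.approx(prof[1, 0])      # zero loading
        assert prof[1, 1] > prof[0, 1]                      # positive loading
        assert prof[0, 2] > prof[1, 2]                      # negative loading
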