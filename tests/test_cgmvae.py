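import numpy as np
import pandas as pd
import pytest

from cogmix import cgmvae as cg
from cogmix import synthetic as syn


@pytest.fixture(scope="module")
def small_state():
    rng = np.random.default_rng(0)
    cfg = cg.CGMVAEConfig(hidden_dim=16, latent_dim=3, n_components=4, epochs=1,
                          seed=0)
    params, bn = cg._init_params(cfg, rng)
    return cg.CGMVAEState(params=params, bn_state=bn, config=cfg)


def batch(n=12, seed=1):
    rng = np.random.default_rng(seed)
    x = rng.uniform(size=(n, 54))
    c = np.eye(3)[rng.integers(0, 3, size=n)]
    return x, c


class TestEncodeDecode:
    def test_shapes_and_softmax_normalization(self, small_state):
        x, c = batch()
        q, mu, lv = cg.encode(x, c, small_state)
        assert q.shape == (12, 4) and mu.shape == (12, 4, 3) and lv.shape == (12, 4, 3)
        np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-6)

    def test_single_component_membership_is_one(self):
        rng = np.random.default_rng(2)
        cfg = cg.CGMVAEConfig(hidden_dim=8, latent_dim=2, n_components=1, epochs=1)
        params, bn = cg._init_params(cfg, rng)
        state = cg.CGMVAEState(params=params, bn_state=bn, config=cfg)
        x, c = batch(5)
        q, _, _ = cg.encode(x, c, state)
        np.testing.assert_allclose(q, 1.0)

    def test_nan_input_rejected(self, small_state):
        x, c = batch()
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            cg.encode(x, c, small_state)

    def test_condition_is_consumed(self, small_state):
        x, _ = batch()
        c1 = np.tile(np.eye(3)[0], (12, 1))
        c2 = np.tile(np.eye(3)[2], (12, 1))
        q1, mu1, _ = cg.encode(x, c1, small_state)
        q2, mu2, _ = cg.encode(x, c2, small_state)
        assert np.abs(mu1 - mu2).mean() > 0

    def test_decode_range_and_shape(self, small_state):
        z = np.random.default_rng(3).normal(size=(7, 3))
        c = np.eye(3)[np.zeros(7, int)]
        xhat = cg.decode(z, c, small_state)
        assert xhat.shape == (7, 54)
        assert np.all(xhat >= 0) and np.all(xhat <= 1)

    def test_conditioning_changes_reconstruction(self, small_state):
        z = np.random.default_rng(4).normal(size=(6, 3))
        r1 = cg.decode(z, np.eye(3)[np.zeros(6, int)], small_state)
        r2 = cg.decode(z, np.eye(3)[np.full(6, 2)], small_state)
        assert np.abs(r1 - r2).mean() > 0


class TestLatentOps:
    def test_reparameterize_identities(self):
        mu = np.array([[1.0, -2.0]])
        lv = np.zeros((1, 2))
        np.testing.assert_allclose(cg.reparameterize(mu, lv, np.zeros((1, 2))), mu)
        np.testing.assert_allclose(
            cg.reparameterize(mu, lv, np.ones((1, 2))), mu + 1.0)

    def test_reparameterize_monte_carlo_mean(self):
        rng = np.random.default_rng(5)
        mu, sd = 0.7, 1.3
        draws = cg.reparameterize(mu, 2 * np.log(sd), rng.standard_normal(10000))
        assert abs(draws.mean() - mu) < 3 * sd / 100

    def test_aggregate_latent(self):
        z = np.array([[[0.0, 0.0], [2.0, 2.0]]])  # (1, K=2, D=2)
        one_hot = np.array([[0.0, 1.0]])
        np.testing.assert_allclose(cg.aggregate_latent(one_hot, z), [[2.0, 2.0]])
        np.testing.assert_allclose(
            cg.aggregate_latent(np.array([[0.5, 0.5]]), z), [[1.0, 1.0]])
        same = np.tile(np.array([[[3.0, 1.0]]]), (1, 2, 1))
        np.testing.assert_allclose(
            cg.aggregate_latent(np.array([[0.9, 0.1]]), same), [[3.0, 1.0]])


class TestKL:
    def test_zero_for_matching_distributions(self):
        K, D = 3, 4
        mu_p = np.random.default_rng(6).normal(size=(K, D))
        lv_p = np.random.default_rng(7).normal(size=(K, D))
        q = np.full((5, K), 1.0 / K)
        mu = np.tile(mu_p, (5, 1, 1))
        lv = np.tile(lv_p, (5, 1, 1))
        kld, klc = cg.kl_mixture(q, mu, lv, mu_p, lv_p)
        np.testing.assert_allclose(kld, 0.0, atol=1e-12)
        assert klc == pytest.approx(0.0, abs=1e-12)  # uniform q

    def test_unit_shift_closed_form(self):
        """K=1: KL(N(1,1) || N(0,1)) = mu^2/2 = 0.5 per dimension."""
        q = np.ones((2, 1))
        mu = np.ones((2, 1, 1))
        lv = np.zeros((2, 1, 1))
        kld, klc = cg.kl_mixture(q, mu, lv, np.zeros((1, 1)), np.zeros((1, 1)))
        assert kld[0] == pytest.approx(0.5, abs=1e-12)
        assert klc == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative(self):
        rng = np.random.default_rng(8)
        q = rng.dirichlet(np.ones(3), size=6)
        kld, klc = cg.kl_mixture(q, rng.normal(size=(6, 3, 2)),
                                 rng.normal(size=(6, 3, 2)),
                                 rng.normal(size=(3, 2)), rng.normal(size=(3, 2)))
        assert np.all(kld >= 0) and klc >= 0


class TestLoss:
    def test_beta_zero_total_is_reconstruction(self, small_state):
        x, c = batch()
        lb = cg.elbo_loss(x, c, small_state, beta=0.0)
        assert lb.total == pytest.approx(lb.reconstruction, abs=1e-12)

    def test_decomposition_and_floor(self, small_state):
        x, c = batch()
        cfg = small_state.config
        rng = np.random.default_rng(9)
        eps = rng.standard_normal((12, cfg.n_components, cfg.latent_dim))
        lb = cg.elbo_loss(x, c, small_state, eps=eps)
        assert lb.total == pytest.approx(
            lb.reconstruction + cfg.beta * lb.kl_clamped, abs=1e-6)
        assert lb.kl_clamped >= cfg.latent_dim * cfg.free_bits - 1e-9
        assert lb.total >= lb.reconstruction  # beta > 0, KL >= 0

    def test_perfect_prior_match_hits_clamp_floor(self):
        """With posterior == prior the Gaussian KL clamps at D * free_bits."""
        rng = np.random.default_rng(10)
        cfg = cg.CGMVAEConfig(hidden_dim=8, latent_dim=2, n_components=2,
                              free_bits=0.1, beta=0.5, epochs=1)
        params, bn = cg._init_params(cfg, rng)
        params["head_mu_W"] *= 0.0
        params["head_lv_W"] *= 0.0
        params["head_mu_b"] *= 0.0
        params["head_lv_b"] *= 0.0
        params["mu_prior"] *= 0.0
        params["logvar_prior"] *= 0.0
        state = cg.CGMVAEState(params=params, bn_state=bn, config=cfg)
        x, c = batch(6)
        lb = cg.elbo_loss(x, c, state)
        assert lb.kl_per_dim == pytest.approx(np.zeros(2), abs=1e-12)
        assert lb.kl_clamped == pytest.approx(
            cfg.latent_dim * cfg.free_bits + lb.kl_categorical, abs=1e-12)


class TestClipAndAdam:
    def test_clip_contract(self):
        rng = np.random.default_rng(11)
        grads = {"a": rng.normal(size=(5, 5)), "b": rng.normal(size=7)}
        clipped, norm = cg.clip_gradients(grads, 0.644)
        post = np.sqrt(sum(float((g ** 2).sum()) for g in clipped.values()))
        assert post <= 0.644 + 1e-6
        small = {"a": np.full(3, 1e-4)}
        same, _ = cg.clip_gradients(small, 0.644)
        np.testing.assert_array_equal(same["a"], small["a"])


class TestTraining:
    def test_same_seed_identical_history(self, profile_dataset_4):
        cfg = cg.CGMVAEConfig(hidden_dim=16, latent_dim=3, n_components=4,
                              epochs=3, seed=12)
        _, h1 = cg.train(profile_dataset_4, cfg)
        _, h2 = cg.train(profile_dataset_4, cfg)
        pd.testing.assert_frame_equal(h1, h2)

    def test_zero_learning_rate_freezes_parameters(self, profile_dataset_4):
        cfg = cg.CGMVAEConfig(hidden_dim=16, latent_dim=3, n_components=4,
                              epochs=2, seed=13, learning_rate=0.0, min_lr=0.0)
        state, hist = cg.train(profile_dataset_4, cfg)
        rng = np.random.default_rng(cfg.seed)
        cg._stratified_split(cg.preprocess(profile_dataset_4)[2],
                             cfg.val_fraction, rng)
        init_params, _ = cg._init_params(cfg, rng)
        for k, v in init_params.items():
            np.testing.assert_array_equal(state.params[k], v)
        # weights frozen: validation can drift only through batch-norm
        # running statistics, never through parameter updates
        assert np.isfinite(hist["val_total"]).all()

    def test_validation_loss_improves(self, tiny_trained_state):
        _, history = tiny_trained_state
        assert history["val_total"].min() < history["val_total"].iloc[0]

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_aborts(self, profile_dataset_4):
        cfg = cg.CGMVAEConfig(hidden_dim=16, latent_dim=3, n_components=4,
                              epochs=2, seed=14, learning_rate=float("inf"),
                              grad_clip=0.0)
        with pytest.raises(RuntimeError, match="diverged"):
            cg.train(profile_dataset_4, cfg)

    def test_overfit_tiny_autoencoding_batch(self):
        """Eight inputs, D=2: the model reconstructs its training batch."""
        rng = np.random.default_rng(15)
        bank = syn.make_separated_bank(4, separation=4.0, seed=99)
        ds = syn.simulate_profiles(8, bank, seed=15)
        cfg = cg.CGMVAEConfig(hidden_dim=48, latent_dim=2, n_components=2,
                              epochs=400, batch_size=8, seed=15,
                              learning_rate=3e-3, beta=0.01, free_bits=0.0,
                              grad_clip=5.0, scheduler_patience=100)
        state, hist = cg.train(ds, cfg, val_data=ds)
        X, C, _, _ = cg.preprocess(ds, wm_max=state.wm_max)
        q, mu, _ = cg.encode(X, C, state)
        z = cg.aggregate_latent(np.asarray(q), np.asarray(mu))
        xhat = cg.decode(z, C, state)
        assert float(((X - xhat) ** 2).mean()) < 0.05


class TestInference:
    def test_membership_rows_sum_to_one(self, profile_dataset_4, tiny_trained_state):
        state, _ = tiny_trained_state
        mm = cg.membership(profile_dataset_4, state)
        np.testing.assert_allclose(mm.memberships.sum(axis=1), 1.0, atol=1e-6)
        assert mm.hard_labels.shape == (profile_dataset_4.n,)

    def test_embedding_deterministic(self, profile_dataset_4, tiny_trained_state):
        state, _ = tiny_trained_state
        e1 = cg.latent_embedding(profile_dataset_4, state)
        e2 = cg.latent_embedding(profile_dataset_4, state)
        np.testing.assert_array_equal(e1, e2)
        assert e1.shape == (profile_dataset_4.n, state.config.latent_dim)

    def test_one_hot_membership_embedding_equals_component_mean(self):
        q = np.array([[0.0, 1.0]])
        mu = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        emb = (q[:, :, None] * mu).sum(axis=1)
        np.testing.assert_allclose(emb, [[3.0, 4.0]])

    def test_checkpoint_roundtrip(self, tiny_trained_state, tmp_path):
        state, _ = tiny_trained_state
        path = tmp_path / "ckpt.npz"
        cg.save_checkpoint(state, path)
        back = cg.load_checkpoint(path)
        for k, v in state.params.items():
            np.testing.assert_array_equal(back.params[k], v)
        assert back.config == state.config


class TestHPO:
    def test_single_trial_and_collapsed_space(self, profile_dataset_4):
        space = {"latent_dim": (3, 3), "n_components": (4, 4),
                 "learning_rate": (1e-3, 1e-3), "free_bits": (0.05, 0.05)}
        base = cg.CGMVAEConfig(hidden_dim=16, latent_dim=3, n_components=4,
                               epochs=2)
        best, trials, state = cg.hyperparameter_search(
            profile_dataset_4, space, n_trials=1, seed=0, base_config=base)
        assert (best.latent_dim, best.n_components) == (3, 4)
        assert best.learning_rate == pytest.approx(1e-3)
        assert len(trials) == 1
        assert trials["val_loss"].min() <= trials["val_loss"].median()
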