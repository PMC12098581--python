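"""Conditional Gaussian-mixture variational autoencoder.

The encoder maps the concatenation of the 54-feature response vector x and a
one-hot age-bin condition c through fully connected blocks (linear -> ReLU ->
batch norm) into three heads: mixture logits q(y|x, c) over K components,
and per-component Gaussian means and log-variances of shape (batch, K, D).
A latent sample is drawn from every component with the reparameterization
trick z_k = mu_k + sigma_k * eps and aggregated as z = sum_k q_k z_k. The
decoder mirrors the encoder on [z, c] with a sigmoid output head (all
features are binary or normalized to [0, 1]; the working-memory span score
is max-normalized during preprocessing).

The prior p(z|c) is a learnable Gaussian mixture with per-component
mu_prior / logvar_prior. The KL between a mixture posterior and a mixture
prior has no closed form; the standard GMVAE upper bound is used: the
q(y)-weighted component-wise Gaussian KL plus the categorical KL of q(y) to
a uniform component prior. Training minimizes

    total = MSE(x, x_hat) + beta * (sum_d max(free_bits, KL_d) + KL_cat)

where KL_d is the per-latent-dimension Gaussian KL averaged over the batch;
the free-bits floor keeps every latent dimension carrying a minimum of
information and is not applied to the categorical term.

Everything is implemented with `autograd` on NumPy arrays; optimization is
a hand-rolled Adam with weight decay, global-norm gradient clipping and a
reduce-on-plateau learning-rate schedule, all seeded and deterministic on a
single device.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
import pandas as pd
from autograd import value_and_grad
from autograd.tracer import getval

from .schema import ItemResponseDataset
from .synthetic import bin_ages

__all__ = [
    "CGMVAEConfig",
    "CGMVAEState",
    "LossBreakdown",
    "MembershipMatrix",
    "encode",
    "reparameterize",
    "aggregate_latent",
    "decode",
    "kl_mixture",
    "elbo_loss",
    "train",
    "hyperparameter_search",
    "membership",
    "latent_embedding",
    "clip_gradients",
    "preprocess",
]


@dataclass(frozen=True)
class CGMVAEConfig:
    """Architecture and training hyperparameters.

    The defaults are the selected configuration reported for the full-scale
    analysis (hidden 201, latent 58, K = 10, beta 0.051, free bits 0.048,
    lr 9.68e-4, weight decay 4.0e-5, gradient clip 0.644); desk-scale runs
    override the sizes.
    """

    input_dim: int = 54
    condition_dim: int = 3
    hidden_dim: int = 201
    latent_dim: int = 58
    n_components: int = 10
    beta: float = 0.051
    free_bits: float = 0.048
    learning_rate: float = 9.68e-4
    weight_decay: float = 4.00e-5
    grad_clip: float = 0.644
    batch_size: int = 128
    epochs: int = 50
    seed: int = 0
    n_hidden_layers: int = 2
    val_fraction: float = 0.2
    scheduler_factor: float = 0.5
    scheduler_patience: int = 5
    min_lr: float = 1e-6
    output_head: str = "sigmoid"  # or "linear"

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")
        if self.n_components < 1 or self.latent_dim < 1:
            raise ValueError("n_components and latent_dim must be >= 1")
        if self.free_bits < 0:
            raise ValueError("free_bits must be non-negative")


def replace_config(cfg: CGMVAEConfig, **kw) -> CGMVAEConfig:
    return dataclasses.replace(cfg, **kw)


def config_to_dict(cfg: CGMVAEConfig) -> dict:
    return dataclasses.asdict(cfg)


@dataclass
class CGMVAEState:
    """Weights, batch-norm running statistics and preprocessing constants."""

    params: dict
    bn_state: dict
    config: CGMVAEConfig
    wm_max: float = 1.0
    epoch: int = 0

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}


@dataclass
class LossBreakdown:
    total: float
    reconstruction: float
    kl_raw: float
    kl_clamped: float
    kl_per_dim: np.ndarray
    kl_categorical: float


@dataclass
class MembershipMatrix:
    """Fuzzy memberships q(y|x, c); hard labels are the row-wise argmax
    (ties broken toward the lowest component index)."""

    memberships: np.ndarray

    def __post_init__(self) -> None:
        U = np.asarray(self.memberships, dtype=float)
        if not np.allclose(U.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("membership rows must sum to 1")
        self.memberships = U

    @property
    def hard_labels(self) -> np.ndarray:
        return self.memberships.argmax(axis=1)


# --------------------------------------------------------------------------
# initialization
# --------------------------------------------------------------------------

def _init_params(cfg: CGMVAEConfig, rng: np.random.Generator) -> tuple[dict, dict]:
    def glorot(n_in, n_out):
        s = math.sqrt(2.0 / (n_in + n_out))
        return rng.normal(0.0, s, size=(n_in, n_out))

    H, D, K = cfg.hidden_dim, cfg.latent_dim, cfg.n_components
    p: dict = {}
    bn: dict = {}
    dims_in = cfg.input_dim + cfg.condition_dim
    for side, first in (("enc", dims_in), ("dec", D + cfg.condition_dim)):
        d = first
        for layer in range(cfg.n_hidden_layers):
            p[f"{side}_W{layer}"] = glorot(d, H)
            p[f"{side}_b{layer}"] = np.zeros(H)
            p[f"{side}_bn{layer}_g"] = np.ones(H)
            p[f"{side}_bn{layer}_b"] = np.zeros(H)
            bn[f"{side}_bn{layer}_mean"] = np.zeros(H)
            bn[f"{side}_bn{layer}_var"] = np.ones(H)
            d = H
    p["head_logits_W"], p["head_logits_b"] = glorot(H, K), np.zeros(K)
    p["head_mu_W"], p["head_mu_b"] = glorot(H, K * D), np.zeros(K * D)
    p["head_lv_W"], p["head_lv_b"] = glorot(H, K * D), np.full(K * D, -1.0)
    p["out_W"], p["out_b"] = glorot(H, cfg.input_dim), np.zeros(cfg.input_dim)
    p["mu_prior"] = rng.normal(0.0, 0.5, size=(K, D))
    p["logvar_prior"] = np.zeros((K, D))
    return p, bn


# --------------------------------------------------------------------------
# network pieces (autograd-compatible: params may be ArrayBoxes)
# --------------------------------------------------------------------------

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def _trunk(params, bn_state, side, h, cfg, training):
    for layer in range(cfg.n_hidden_layers):
        h = anp.dot(h, params[f"{side}_W{layer}"]) + params[f"{side}_b{layer}"]
        h = anp.maximum(h, 0.0)
        mkey, vkey = f"{side}_bn{layer}_mean", f"{side}_bn{layer}_var"
        if training:
            mu = anp.mean(h, axis=0)
            var = anp.var(h, axis=0)
            bn_state[mkey] = (1 - _BN_MOMENTUM) * bn_state[mkey] + _BN_MOMENTUM * getval(mu)
            bn_state[vkey] = (1 - _BN_MOMENTUM) * bn_state[vkey] + _BN_MOMENTUM * getval(var)
        else:
            mu, var = bn_state[mkey], bn_state[vkey]
        h = (h - mu) / anp.sqrt(var + _BN_EPS)
        h = h * params[f"{side}_bn{layer}_g"] + params[f"{side}_bn{layer}_b"]
    return h


def _softmax(logits):
    z = logits - anp.max(logits, axis=-1, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=-1, keepdims=True)


def _encode_params(params, bn_state, x, c, cfg, training):
    h = _trunk(params, bn_state, "enc", anp.concatenate([x, c], axis=1), cfg, training)
    K, D = cfg.n_components, cfg.latent_dim
    q_y = _softmax(anp.dot(h, params["head_logits_W"]) + params["head_logits_b"])
    mu = anp.reshape(anp.dot(h, params["head_mu_W"]) + params["head_mu_b"], (-1, K, D))
    lv = anp.reshape(anp.dot(h, params["head_lv_W"]) + params["head_lv_b"], (-1, K, D))
    lv = anp.clip(lv, -8.0, 8.0)
    return q_y, mu, lv


def encode(x: np.ndarray, c: np.ndarray, state: CGMVAEState, training: bool = False):
    """Recognition network: (q_y, mu, logvar) with shapes (n, K), (n, K, D)."""
    x, c = np.atleast_2d(np.asarray(x, float)), np.atleast_2d(np.asarray(c, float))
    if np.isnan(x).any() or np.isnan(c).any():
        raise ValueError("NaN in encoder input")
    if x.shape[1] != state.config.input_dim:
        raise ValueError(f"expected {state.config.input_dim} features")
    return _encode_params(state.params, state.bn_state, x, c, state.config, training)


def reparameterize(mu, logvar, eps):
    """z = mu + sigma * eps, elementwise and differentiable in mu/logvar."""
    return mu + anp.exp(0.5 * logvar) * eps


def aggregate_latent(q_y, z_components):
    """Weighted sum of per-component samples: z = sum_k q_y[:, k] z_k."""
    return anp.sum(q_y[:, :, None] * z_components, axis=1)


def _decode_params(params, bn_state, z, c, cfg, training):
    h = _trunk(params, bn_state, "dec", anp.concatenate([z, c], axis=1), cfg, training)
    out = anp.dot(h, params["out_W"]) + params["out_b"]
    if cfg.output_head == "sigmoid":
        out = 1.0 / (1.0 + anp.exp(-out))
    return out


def decode(z: np.ndarray, c: np.ndarray, state: CGMVAEState, training: bool = False):
    """Generative network: reconstruction x_hat with 54 features."""
    z, c = np.atleast_2d(np.asarray(z, float)), np.atleast_2d(np.asarray(c, float))
    if z.shape[1] != state.config.latent_dim:
        raise ValueError(f"expected latent dimension {state.config.latent_dim}")
    return _decode_params(state.params, state.bn_state, z, c, state.config, training)


def kl_mixture(q_y, mu, logvar, mu_prior, logvar_prior):
    """(per-dimension Gaussian KL vector (D,), categorical KL scalar).

    Gaussian part: sum_k q_k KL(N(mu_k, sigma_k^2) || N(mu_prior_k,
    sigma_prior_k^2)) per latent dimension, averaged over the batch.
    Categorical part: KL(q_y || uniform(K)), averaged over the batch.
    Both are non-negative.
    """
    var_ratio = anp.exp(logvar - logvar_prior[None, :, :])
    delta2 = (mu - mu_prior[None, :, :]) ** 2 / anp.exp(logvar_prior)[None, :, :]
    kl_comp = 0.5 * (logvar_prior[None, :, :] - logvar + var_ratio + delta2 - 1.0)
    kl_per_dim = anp.mean(anp.sum(q_y[:, :, None] * kl_comp, axis=1), axis=0)  # (D,)
    K = q_y.shape[1]
    qc = anp.clip(q_y, 1e-12, 1.0)
    kl_cat = anp.mean(anp.sum(qc * (anp.log(qc) + math.log(K)), axis=1))
    return kl_per_dim, kl_cat


def _loss_params(params, bn_state, x, c, eps, cfg, training, aux=None):
    q_y, mu, lv = _encode_params(params, bn_state, x, c, cfg, training)
    z = aggregate_latent(q_y, reparameterize(mu, lv, eps))
    xhat = _decode_params(params, bn_state, z, c, cfg, training)
    recon = anp.mean((x - xhat) ** 2)
    kl_per_dim, kl_cat = kl_mixture(q_y, mu, lv, params["mu_prior"], params["logvar_prior"])
    kl_raw = anp.sum(kl_per_dim) + kl_cat
    kl_clamped = anp.sum(anp.maximum(cfg.free_bits, kl_per_dim)) + kl_cat
    total = recon + cfg.beta * kl_clamped
    if aux is not None:
        aux.update(
            recon=float(getval(recon)), kl_raw=float(getval(kl_raw)),
            kl_clamped=float(getval(kl_clamped)),
            kl_per_dim=np.asarray(getval(kl_per_dim), dtype=float),
            kl_cat=float(getval(kl_cat)), total=float(getval(total)),
        )
    return total


def elbo_loss(
    x: np.ndarray,
    c: np.ndarray,
    state: CGMVAEState,
    beta: float | None = None,
    free_bits: float | None = None,
    eps: np.ndarray | None = None,
    training: bool = False,
) -> LossBreakdown:
    """Evaluate the training objective on one batch.

    ``eps`` is the (n, K, D) reparameterization noise; zero (the default)
    evaluates at the posterior means.
    """
    import types

    cfg = state.config
    if beta is not None or free_bits is not None:
        # a plain namespace so beta = 0 (pure-reconstruction probe) is allowed
        d = config_to_dict(cfg)
        if beta is not None:
            d["beta"] = beta
        if free_bits is not None:
            d["free_bits"] = free_bits
        cfg = types.SimpleNamespace(**d)
    x, c = np.atleast_2d(np.asarray(x, float)), np.atleast_2d(np.asarray(c, float))
    if eps is None:
        eps = np.zeros((x.shape[0], cfg.n_components, cfg.latent_dim))
    aux: dict = {}
    bn = {k: v.copy() for k, v in state.bn_state.items()}
    _loss_params(state.params, bn, x, c, eps, cfg, training, aux)
    return LossBreakdown(
        total=aux["total"], reconstruction=aux["recon"], kl_raw=aux["kl_raw"],
        kl_clamped=aux["kl_clamped"], kl_per_dim=aux["kl_per_dim"],
        kl_categorical=aux["kl_cat"],
    )


# --------------------------------------------------------------------------
# optimization
# --------------------------------------------------------------------------

def clip_gradients(grads: dict, max_norm: float) -> tuple[dict, float]:
    """Scale gradients so the global L2 norm is at most ``max_norm``."""
    total = math.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
    if max_norm is not None and max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        grads = {k: g * scale for k, g in grads.items()}
        return grads, max_norm
    return grads, total


class _Adam:
    def __init__(self, params: dict, lr: float, weight_decay: float,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd, self.b1, self.b2, self.eps = lr, weight_decay, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> dict:
        self.t += 1
        out = {}
        for k, p in params.items():
            g = grads[k] + self.wd * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            out[k] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


def preprocess(data: ItemResponseDataset, wm_max: float | None = None):
    """(X, C, bin_index, wm_max): features in [0, 1], one-hot age-bin."""
    X = data.responses.copy()
    wm_idx = [j for j, it in enumerate(data.schema.items)
              if it.scale == "nonnegative_continuous"]
    if wm_max is None:
        wm_max = max(float(X[:, wm_idx].max()), 1e-12) if wm_idx else 1.0
    X[:, wm_idx] = np.clip(X[:, wm_idx] / wm_max, 0.0, 1.0)
    bin_index, _ = bin_ages(data.ages)
    C = np.eye(3)[bin_index]
    return X, C, bin_index, wm_max


def _stratified_split(bin_index, val_fraction, rng):
    train_idx, val_idx = [], []
    for b in np.unique(bin_index):
        idx = np.flatnonzero(bin_index == b)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(len(idx) * val_fraction)))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def train(
    data: ItemResponseDataset,
    config: CGMVAEConfig,
    val_data: ItemResponseDataset | None = None,
) -> tuple[CGMVAEState, pd.DataFrame]:
    """Mini-batch Adam training with validation monitoring.

    The split is 80/20 stratified by age bin (unless ``val_data`` is given);
    the best-validation weights are retained in the returned state. History
    holds per-epoch train/validation total, reconstruction and KL terms.
    Raises RuntimeError on divergence (non-finite loss).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    X, C, bins, wm_max = preprocess(data)
    if val_data is not None:
        Xt, Ct = X, C
        Xv, Cv, _, _ = preprocess(val_data, wm_max=wm_max)
    else:
        tr, va = _stratified_split(bins, cfg.val_fraction, rng)
        Xt, Ct, Xv, Cv = X[tr], C[tr], X[va], C[va]
    params, bn_state = _init_params(cfg, rng)
    opt = _Adam(params, cfg.learning_rate, cfg.weight_decay)
    loss_grad = value_and_grad(
        lambda p, bx, bc, be, bn, aux: _loss_params(p, bn, bx, bc, be, cfg, True, aux)
    )
    history = []
    best_val, best_params, best_bn, best_epoch = np.inf, None, None, -1
    lr, plateau = cfg.learning_rate, 0
    n_tr = Xt.shape[0]
    K, D = cfg.n_components, cfg.latent_dim
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_tr)
        tr_terms = []
        for start in range(0, n_tr, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs >= 2 rows
            eps = rng.standard_normal((len(idx), K, D))
            aux: dict = {}
            _, grads = loss_grad(params, Xt[idx], Ct[idx], eps, bn_state, aux)
            if not np.isfinite(aux["total"]):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={aux['total']})"
                )
            grads, _ = clip_gradients(grads, cfg.grad_clip)
            opt.lr = lr
            params = opt.step(params, grads)
            tr_terms.append((aux["total"], aux["recon"], aux["kl_clamped"]))
        state_now = CGMVAEState(params=params, bn_state=bn_state, config=cfg,
                                wm_max=wm_max, epoch=epoch)
        val = elbo_loss(Xv, Cv, state_now)
        tr_mean = np.mean(np.asarray(tr_terms), axis=0)
        history.append({
            "epoch": epoch, "train_total": tr_mean[0], "train_recon": tr_mean[1],
            "train_kl": tr_mean[2], "val_total": val.total,
            "val_recon": val.reconstruction, "val_kl": val.kl_clamped, "lr": lr,
        })
        if val.total < best_val - 1e-12:
            best_val, best_epoch = val.total, epoch
            best_params = {k: np.array(getval(v), copy=True) for k, v in params.items()}
            best_bn = {k: v.copy() for k, v in bn_state.items()}
            plateau = 0
        else:
            plateau += 1
            if plateau > cfg.scheduler_patience:
                lr = max(lr * cfg.scheduler_factor, cfg.min_lr)
                plateau = 0
    if best_params is None:  # zero epochs or never improved
        best_params = {k: np.array(getval(v), copy=True) for k, v in params.items()}
        best_bn, best_epoch = {k: v.copy() for k, v in bn_state.items()}, cfg.epochs - 1
    state = CGMVAEState(params=best_params, bn_state=best_bn, config=cfg,
                        wm_max=wm_max, epoch=best_epoch)
    return state, pd.DataFrame(history)


def hyperparameter_search(
    data: ItemResponseDataset,
    space: dict | None = None,
    n_trials: int = 10,
    seed: int = 0,
    base_config: CGMVAEConfig | None = None,
) -> tuple[CGMVAEConfig, pd.DataFrame, CGMVAEState]:
    """Seeded random search over latent_dim, n_components, lr and free bits.

    Minimizes validation total loss; the winning configuration is then
    retrained on the full dataset and returned alongside the trial log.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    space = space or {
        "latent_dim": (4, 64),
        "n_components": (2, 15),
        "learning_rate": (1e-4, 1e-2),
        "free_bits": (0.01, 0.2),
    }
    base = base_config or CGMVAEConfig()
    rng = np.random.default_rng(seed)
    trials, best = [], None
    for t in range(n_trials):
        lo, hi = space["latent_dim"]
        D = int(rng.integers(lo, hi + 1))
        lo, hi = space["n_components"]
        K = int(rng.integers(lo, hi + 1))
        lo, hi = space["learning_rate"]
        lr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        lo, hi = space["free_bits"]
        fb = float(rng.uniform(lo, hi))
        cfg = replace_config(base, latent_dim=D, n_components=K,
                             learning_rate=lr, free_bits=fb,
                             seed=int(rng.integers(2**31 - 1)))
        try:
            _, hist = train(data, cfg)
            val = float(hist["val_total"].min())
        except RuntimeError as exc:
            trials.append({"trial": t, "latent_dim": D, "n_components": K,
                           "learning_rate": lr, "free_bits": fb,
                           "val_loss": np.nan, "error": repr(exc)})
            continue
        trials.append({"trial": t, "latent_dim": D, "n_components": K,
                       "learning_rate": lr, "free_bits": fb,
                       "val_loss": val, "error": ""})
        if best is None or val < best[0]:
            best = (val, cfg)
    if best is None:
        raise RuntimeError("all hyperparameter trials failed")
    final_state, _ = train(data, best[1])
    return best[1], pd.DataFrame(trials), final_state


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def _as_xc(data, c, state):
    if isinstance(data, ItemResponseDataset):
        X, C, _, _ = preprocess(data, wm_max=state.wm_max)
        return X, C
    return np.atleast_2d(np.asarray(data, float)), np.atleast_2d(np.asarray(c, float))


def membership(data, state: CGMVAEState, c: np.ndarray | None = None) -> MembershipMatrix:
    """Fuzzy membership matrix q(y | x, c) in evaluation mode."""
    X, C = _as_xc(data, c, state)
    q_y, _, _ = encode(X, C, state, training=False)
    return MembershipMatrix(memberships=np.asarray(q_y))


def latent_embedding(data, state: CGMVAEState, c: np.ndarray | None = None) -> np.ndarray:
    """Deterministic latent features: the q(y)-weighted posterior means."""
    X, C = _as_xc(data, c, state)
    q_y, mu, _ = encode(X, C, state, training=False)
    return np.asarray((q_y[:, :, None] * mu).sum(axis=1))


def save_checkpoint(state: CGMVAEState, path) -> None:
    """Single-file archive of weights, batch-norm state and config."""
    arrays = {f"p__{k}": v for k, v in state.params.items()}
    arrays.update({f"bn__{k}": v for k, v in state.bn_state.items()})
    np.savez(path, wm_max=state.wm_max, epoch=state.epoch,
             config=np.array([repr(config_to_dict(state.config))]), **arrays)


def load_checkpoint(path) -> CGMVAEState:
    import ast

    with np.load(path, allow_pickle=False) as z:
        cfg = CGMVAEConfig(**ast.literal_eval(str(z["config"][0])))
        params = {k[3:]: z[k] for k in z.files if k.startswith("p__")}
        bn = {k[4:]: z[k] for k in z.files if k.startswith("bn__")}
        return CGMVAEState(params=params, bn_state=bn, config=cfg,
                           wm_max=float(z["wm_max"]), epoch=int(z["epoch"]))
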