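"""Factor mixture models with a concomitant age-bin covariate, fitted by EM.

Model family
------------
Latent class k has a factor distribution; binary item j follows
``P(y=1 | eta) = logistic(tau_j + lambda_j' eta)`` and continuous items are
linear-Gaussian in the factor with class-invariant residual variances. Two
variants share class-invariant thresholds and loadings:

* **FMM-1** (latent class factor analysis): the within-class factor
  covariance is fixed at zero, so class k places the factor at the point
  ``alpha_k`` and the within-class likelihood needs no integration.
* **FMM-2** (mixture factor analysis): the factor is N(alpha_k, Psi_k) with
  class-specific diagonal Psi_k, integrated by Gauss-Hermite quadrature.

Class membership may depend on the centered age-bin code c in {-1, 0, +1}
through a multinomial logistic model (reference = last class) whose
coefficients are re-estimated inside the M-step.

Baselines: :func:`fit_lca` (latent class / profile analysis with
class-specific continuous variances) and :func:`fit_fa` (one-class
full-information factor analysis). :func:`model_ladder` fits the grids and
selects the BIC winner.

EM is implemented as generalized EM: each M-step block (covariate
coefficients, measurement parameters, class factor parameters) performs
damped Newton updates with backtracking on the expected complete-data
log-likelihood, so the observed log-likelihood is monotone non-decreasing.
For FMM-2 the likelihood is *defined* through the fixed quadrature rule
(an exact finite mixture over class-by-node components), which keeps the
monotonicity guarantee exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp

from .schema import ItemResponseDataset
from .synthetic import bin_ages, class_probabilities

__all__ = [
    "FMMSpec",
    "FMMParams",
    "FMMFit",
    "LadderResult",
    "ConvergenceError",
    "information_criteria",
    "odds_ratio_from_coefficient",
    "fmm_loglik",
    "e_step",
    "m_step_multinomial",
    "fit_lca",
    "fit_fa",
    "fit_fmm",
    "model_ladder",
    "expected_response_profiles",
    "align_alpha",
]

MAX_LOGIT_COEF = 15.0


class ConvergenceError(RuntimeError):
    """No EM restart reached a usable optimum."""


# --------------------------------------------------------------------------
# specifications and parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FMMSpec:
    n_classes: int
    n_factors: int
    variant: Literal["FMM1", "FMM2"] = "FMM1"
    covariate_included: bool = True

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_factors < 1:
            raise ValueError("n_classes and n_factors must be >= 1")
        if self.variant not in ("FMM1", "FMM2"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class FMMParams:
    """Measurement and structural parameters.

    ``tau``: (J,) item thresholds/intercepts; ``lam``: (J, F) loadings;
    ``alpha``: (K, F) class factor means; ``psi``: (K, F) diagonal factor
    variances (all zero for FMM-1); ``sigma2``: residual variances of the
    continuous items; class membership via ``(gamma0, gamma1)`` (each
    (K-1,), reference class last) when a covariate is used, otherwise ``pi``.
    """

    tau: np.ndarray
    lam: np.ndarray
    alpha: np.ndarray
    psi: np.ndarray
    sigma2: np.ndarray
    pi: np.ndarray | None = None
    gamma0: np.ndarray | None = None
    gamma1: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_factors(self) -> int:
        return self.alpha.shape[1]

    def class_log_prior(self, code: np.ndarray | None, n: int) -> np.ndarray:
        """(n, K) log prior class probabilities per person."""
        if self.gamma0 is not None:
            if code is None:
                raise ValueError("covariate model present but no code given")
            p = class_probabilities(code, self.gamma0, self.gamma1)
            return np.log(np.clip(p, 1e-300, None))
        pi = np.clip(self.pi, 1e-300, None)
        return np.broadcast_to(np.log(pi), (n, len(pi))).copy()


@dataclass
class FMMFit:
    spec: FMMSpec
    params: FMMParams
    loglik: float
    n_params: int
    bic: float
    aic: float
    responsibilities: np.ndarray
    converged: bool
    n_iter: int
    n_restarts_used: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    model: str = "FMM"


@dataclass
class LadderResult:
    table: pd.DataFrame
    winner: FMMFit
    fits: dict = field(default_factory=dict)  # (model, K, F) -> FMMFit

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

def information_criteria(loglik: float, n_params: int, n: int) -> tuple[float, float]:
    """BIC = -2 ll + p ln n; AIC = -2 ll + 2 p."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik + n_params * math.log(n), -2.0 * loglik + 2.0 * n_params


def odds_ratio_from_coefficient(b: float) -> tuple[float, float]:
    """Odds ratio and percent change in odds for a log-odds coefficient."""
    if not np.isfinite(b):
        raise ValueError("coefficient must be finite")
    orr = math.exp(b)
    return orr, (orr - 1.0) * 100.0


def _factor_nodes(F: int, variant: str, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Standardized integration nodes (Q, F) and log-weights for N(0, I).

    Gauss-Hermite with 21 nodes for one factor, 9 per dimension for two or
    three; Monte-Carlo (2000 fixed draws) beyond that.
    """
    if F == 1:
        n_nodes = 21
    elif F <= 3:
        n_nodes = 9
    else:
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((2000, F))
        return draws, np.full(2000, -math.log(2000.0))
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = w / np.sqrt(2.0 * math.pi)
    grids = np.meshgrid(*([x] * F), indexing="ij")
    nodes = np.stack([g.ravel() for g in grids], axis=1)
    wgrids = np.meshgrid(*([w] * F), indexing="ij")
    weights = np.prod(np.stack([g.ravel() for g in wgrids], axis=1), axis=1)
    return nodes, np.log(weights)


def _component_logpdf(
    Y: np.ndarray, tau: np.ndarray, lam: np.ndarray, sigma2: np.ndarray,
    H: np.ndarray, bmask: np.ndarray,
) -> np.ndarray:
    """(n, M) log density of each row under factor values H (M, F)."""
    eta = tau[None, :] + H @ lam.T  # (M, J)
    out = np.zeros((Y.shape[0], H.shape[0]))
    if bmask.any():
        eb = eta[:, bmask]
        # y*eta - log(1+exp(eta)), aggregated over items via matmul
        out += Y[:, bmask] @ eb.T - np.logaddexp(0.0, eb).sum(axis=1)[None, :]
    cidx = np.flatnonzero(~bmask)
    for c, j in enumerate(cidx):
        resid = Y[:, j][:, None] - eta[:, j][None, :]
        out += -0.5 * (resid**2 / sigma2[c] + math.log(2.0 * math.pi * sigma2[c]))
    return out


def _design(params: FMMParams, spec: FMMSpec, seed: int = 0):
    """Factor design points per class: (K, Q, F) positions, (Q,) log-weights."""
    K, F = params.alpha.shape
    if spec.variant == "FMM1":
        return params.alpha[:, None, :], np.zeros(1)
    nodes, logw = _factor_nodes(F, spec.variant, seed)
    sd = np.sqrt(np.clip(params.psi, 1e-12, None))  # (K, F)
    return params.alpha[:, None, :] + sd[:, None, :] * nodes[None, :, :], logw


def _log_joint(Y, params, spec, code, bmask) -> tuple[np.ndarray, np.ndarray]:
    """log p(y_i, class k, node q) as (n, K, Q); also per-(k,q) positions."""
    K, F = params.alpha.shape
    H, logw = _design(params, spec)
    Q = H.shape[1]
    flat = H.reshape(K * Q, F)
    comp = _component_logpdf(Y, params.tau, params.lam, params.sigma2, flat, bmask)
    comp = comp.reshape(Y.shape[0], K, Q)
    prior = params.class_log_prior(code, Y.shape[0])  # (n, K)
    return prior[:, :, None] + logw[None, None, :] + comp, H


def fmm_loglik(
    data: ItemResponseDataset | np.ndarray,
    params: FMMParams,
    spec: FMMSpec,
    covariate: np.ndarray | None = None,
) -> float:
    """Observed-data log-likelihood of the mixture of factor models."""
    Y, bmask, code = _prepare(data, spec, covariate)
    if np.any(params.psi < 0):
        raise ValueError("factor variances must be non-negative")
    lj, _ = _log_joint(Y, params, spec, code, bmask)
    return float(logsumexp(lj.reshape(Y.shape[0], -1), axis=1).sum())


def e_step(
    data: ItemResponseDataset | np.ndarray,
    params: FMMParams,
    spec: FMMSpec,
    covariate: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior class responsibilities (n, K); rows sum to 1.

    Uses the log-sum-exp construction throughout, so finite inputs can not
    produce NaN.
    """
    Y, bmask, code = _prepare(data, spec, covariate)
    lj, _ = _log_joint(Y, params, spec, code, bmask)
    ln = logsumexp(lj, axis=2)  # (n, K)
    ln -= logsumexp(ln, axis=1, keepdims=True)
    return np.exp(ln)


def m_step_multinomial(
    responsibilities: np.ndarray,
    centered_code: np.ndarray,
    max_coef: float = MAX_LOGIT_COEF,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximize the expected multinomial log-likelihood of class membership.

    Reference class is the last; coefficients are box-capped at ±``max_coef``
    (a warning is raised when the cap binds, e.g. under perfect separation).
    """
    R = np.asarray(responsibilities, dtype=float)
    code = np.asarray(centered_code, dtype=float)
    if not np.allclose(R.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("responsibility rows must sum to 1")
    n, K = R.shape
    if K == 1:
        return np.empty(0), np.empty(0)
    codes, inv = np.unique(code, return_inverse=True)
    agg = np.zeros((len(codes), K))
    np.add.at(agg, inv, R)  # (B, K) aggregated responsibilities per code value

    def negQ(g):
        g0, g1 = g[: K - 1], g[K - 1 :]
        eta = np.concatenate(
            [g0[None, :] + np.outer(codes, g1), np.zeros((len(codes), 1))], axis=1
        )
        logp = eta - logsumexp(eta, axis=1, keepdims=True)
        val = -(agg * logp).sum()
        p = np.exp(logp)
        resid = agg - agg.sum(axis=1, keepdims=True) * p  # (B, K)
        grad0 = -resid[:, : K - 1].sum(axis=0)
        grad1 = -(codes[:, None] * resid[:, : K - 1]).sum(axis=0)
        return val, np.concatenate([grad0, grad1])

    x0 = np.zeros(2 * (K - 1))
    res = optimize.minimize(
        negQ, x0, jac=True, method="L-BFGS-B",
        bounds=[(-max_coef, max_coef)] * len(x0),
    )
    g0, g1 = res.x[: K - 1], res.x[K - 1 :]
    if np.any(np.abs(res.x) >= max_coef - 1e-9):
        warnings.warn("multinomial coefficients capped (near-degenerate classes)")
    return g0, g1


# --------------------------------------------------------------------------
# M-step blocks (generalized EM with backtracking)
# --------------------------------------------------------------------------

def _binary_Q(B, X, S, Ncounts):
    """Expected binomial loglik per item: B (J,P), X (M,P), S (J,M), N (M,)."""
    eta = B @ X.T
    return (S * eta).sum(axis=1) - (Ncounts[None, :] * np.logaddexp(0.0, eta)).sum(axis=1)


def _newton_logistic_items(B, X, S, Ncounts, n_steps=3):
    """Vectorized damped Newton for per-item aggregated logistic regressions."""
    J, P = B.shape
    for _ in range(n_steps):
        q0 = _binary_Q(B, X, S, Ncounts)
        eta = B @ X.T
        p = expit(eta)
        grad = (S - Ncounts[None, :] * p) @ X  # (J, P)
        w = Ncounts[None, :] * p * (1.0 - p)  # (J, M)
        hess = np.einsum("jm,mi,ml->jil", w, X, X) + 1e-9 * np.eye(P)[None]
        step = np.linalg.solve(hess, grad[:, :, None])[:, :, 0]
        scale = np.ones((J, 1))
        for _bt in range(25):
            q1 = _binary_Q(B + scale * step, X, S, Ncounts)
            bad = q1 < q0 - 1e-12
            if not bad.any():
                break
            scale[bad] *= 0.5
        B = B + scale * step
    return B


def _measurement_update(params, stats, H_flat, bmask, update_lam=True):
    """Update thresholds, loadings and residual variances given factor points.

    ``stats`` holds aggregated E-step moments on the (K*Q,) design:
    ``N`` (M,), ``S`` (J, M) weighted sums, ``SS`` (J_cont, M) weighted
    squared sums for continuous items.
    """
    N, S, SS = stats
    M, F = H_flat.shape
    keep = N > 1e-12
    Xfull = np.concatenate([np.ones((M, 1)), H_flat], axis=1)
    X, Nk = Xfull[keep], N[keep]
    J = params.tau.shape[0]
    bidx = np.flatnonzero(bmask)
    cidx = np.flatnonzero(~bmask)
    tau, lam = params.tau.copy(), params.lam.copy()
    if update_lam:
        B = np.concatenate([tau[bidx, None], lam[bidx]], axis=1)
        B = _newton_logistic_items(B, X, S[bidx][:, keep], Nk)
        tau[bidx], lam[bidx] = B[:, 0], B[:, 1:]
        XtWX = X.T @ (Nk[:, None] * X) + 1e-9 * np.eye(F + 1)
        for c, j in enumerate(cidx):
            b = np.linalg.solve(XtWX, X.T @ S[j][keep])
            tau[j], lam[j] = b[0], b[1:]
    else:  # independence model: loadings pinned at zero
        ptilde = S[bidx].sum(axis=1) / N.sum()
        tau[bidx] = np.log(np.clip(ptilde, 1e-9, None) / np.clip(1 - ptilde, 1e-9, None))
        for c, j in enumerate(cidx):
            tau[j] = S[j].sum() / N.sum()
    sigma2 = params.sigma2.copy()
    ntot = N.sum()
    for c, j in enumerate(cidx):
        fit = Xfull @ np.concatenate([[tau[j]], lam[j]])
        sigma2[c] = max(
            (SS[c].sum() - 2.0 * (fit * S[j]).sum() + (N * fit**2).sum()) / ntot,
            1e-6,
        )
    return replace(params, tau=tau, lam=lam, sigma2=sigma2)


_LOG_SD_MIN, _LOG_SD_MAX = math.log(1e-6), math.log(5.0)


def _alpha_objective(theta, params, stats_k, nodes, bmask, fmm2):
    """Expected loglik of class k's factor parameters (alpha, log sd)."""
    F = params.lam.shape[1]
    alpha = theta[:F]
    sd = np.exp(theta[F:]) if fmm2 else np.zeros(F)
    H = alpha[None, :] + sd[None, :] * nodes  # (Q, F)
    Nq, Sq, SSq = stats_k
    eta = params.tau[:, None] + params.lam @ H.T  # (J, Q)
    bidx = np.flatnonzero(bmask)
    val = (Sq[bidx] * eta[bidx]).sum() - (Nq[None, :] * np.logaddexp(0.0, eta[bidx])).sum()
    cidx = np.flatnonzero(~bmask)
    for c, j in enumerate(cidx):
        val += -0.5 * (
            SSq[c].sum() - 2.0 * (eta[j] * Sq[j]).sum() + (Nq * eta[j] ** 2).sum()
        ) / params.sigma2[c]
    return val


def _update_class_factors(params, per_class_stats, nodes, bmask, fmm2):
    """Damped Newton ascent on each class's factor mean (and log-SD for
    FMM-2) with a positive-semidefinite curvature approximation; backtracking
    guarantees the Q-function never decreases."""
    alpha = params.alpha.copy()
    psi = params.psi.copy()
    F = alpha.shape[1]
    lam = params.lam
    bidx = np.flatnonzero(bmask)
    cidx = np.flatnonzero(~bmask)
    Q = nodes.shape[0]
    for k, stats_k in enumerate(per_class_stats):
        Nq, Sq, SSq = stats_k
        if Nq.sum() < 1e-9:
            continue
        theta = (np.concatenate([alpha[k], 0.5 * np.log(np.clip(psi[k], 1e-12, None))])
                 if fmm2 else alpha[k].copy())
        f_cur = _alpha_objective(theta, params, stats_k, nodes, bmask, fmm2)
        for _ in range(3):
            a, s = theta[:F], (np.exp(theta[F:]) if fmm2 else np.zeros(F))
            H = a[None, :] + s[None, :] * nodes  # (Q, F)
            eta = params.tau[:, None] + lam @ H.T  # (J, Q)
            # d eta_jq / d theta: (J, Q, P)
            dmu = np.broadcast_to(lam[:, None, :], (lam.shape[0], Q, F))
            if fmm2:
                dsd = lam[:, None, :] * (s[None, None, :] * nodes[None, :, :])
                deta = np.concatenate([dmu, dsd], axis=2)
            else:
                deta = dmu
            p = expit(eta[bidx])
            resid = np.zeros_like(eta)
            curv = np.zeros_like(eta)
            resid[bidx] = Sq[bidx] - Nq[None, :] * p
            curv[bidx] = Nq[None, :] * p * (1 - p)
            for c, j in enumerate(cidx):
                resid[j] = (Sq[j] - Nq * eta[j]) / params.sigma2[c]
                curv[j] = Nq / params.sigma2[c]
            grad = np.einsum("jq,jqp->p", resid, deta)
            hess = np.einsum("jq,jqp,jql->pl", curv, deta, deta)
            hess += 1e-8 * np.eye(hess.shape[0])
            step = np.linalg.solve(hess, grad)
            scale = 1.0
            for _bt in range(25):
                cand = theta + scale * step
                cand[:F] = np.clip(cand[:F], -8.0, 8.0)
                if fmm2:
                    cand[F:] = np.clip(cand[F:], _LOG_SD_MIN, _LOG_SD_MAX)
                f_new = _alpha_objective(cand, params, stats_k, nodes, bmask, fmm2)
                if f_new >= f_cur - 1e-12:
                    theta, f_cur = cand, f_new
                    break
                scale *= 0.5
        alpha[k] = theta[:F]
        if fmm2:
            psi[k] = np.exp(2.0 * theta[F:])
    return replace(params, alpha=alpha, psi=psi)


def _renormalize(params: FMMParams, spec: FMMSpec, weights: np.ndarray) -> FMMParams:
    """Apply the identification convention by likelihood-invariant rescaling.

    FMM-1: mixture-weighted mean of alpha is 0 and weighted second moment 1
    per factor. FMM-2: weighted mean 0; scale anchored by the largest-|value|
    loading per factor set to preserve its current magnitude = 1.
    """
    alpha, lam, tau, psi = (params.alpha.copy(), params.lam.copy(),
                            params.tau.copy(), params.psi.copy())
    w = weights / weights.sum()
    for f in range(alpha.shape[1]):
        m = float(w @ alpha[:, f])
        tau += lam[:, f] * m
        alpha[:, f] -= m
        if spec.variant == "FMM1":
            s = math.sqrt(float(w @ alpha[:, f] ** 2))
        else:
            anchor = int(np.argmax(np.abs(lam[:, f])))
            s = abs(lam[anchor, f])
        if s > 1e-8:
            if spec.variant == "FMM1":
                alpha[:, f] /= s
                lam[:, f] *= s
            else:
                lam[:, f] /= s
                alpha[:, f] *= s
                psi[:, f] *= s**2
    return replace(params, alpha=alpha, lam=lam, tau=tau, psi=psi)


# --------------------------------------------------------------------------
# data preparation, initialization, parameter counting
# --------------------------------------------------------------------------

def _prepare(data, spec: FMMSpec | None, covariate):
    if isinstance(data, ItemResponseDataset):
        Y = data.responses
        bmask = data.schema.binary_mask
        if covariate is None and spec is not None and spec.covariate_included:
            _, covariate = bin_ages(data.ages)
    else:
        Y = np.asarray(data, dtype=float)
        bmask = np.array([set(np.unique(col)) <= {0.0, 1.0} for col in Y.T])
    return Y, bmask, covariate


def _initial_params(Y, bmask, spec: FMMSpec, rng: np.random.Generator) -> tuple[FMMParams, np.ndarray]:
    """K-means-on-responses initialization with random perturbation."""
    from sklearn.cluster import KMeans

    n, J = Y.shape
    K, F = spec.n_classes, spec.n_factors
    if K > 1:
        km = KMeans(n_clusters=K, n_init=2, random_state=int(rng.integers(2**31 - 1)))
        hard = km.fit_predict(Y)
        resp = np.full((n, K), 0.1 / max(K - 1, 1))
        resp[np.arange(n), hard] = 0.9
        resp += rng.uniform(0, 0.05, size=resp.shape)
        resp /= resp.sum(axis=1, keepdims=True)
    else:
        resp = np.ones((n, 1))
    pbar = np.clip(Y[:, bmask].mean(axis=0), 0.02, 0.98)
    tau = np.zeros(J)
    tau[bmask] = np.log(pbar / (1 - pbar))
    tau[~bmask] = Y[:, ~bmask].mean(axis=0)
    lam = rng.uniform(0.2, 0.6, size=(J, F))
    alpha = np.linspace(-1.0, 1.0, K)[:, None] * np.ones((1, F))
    alpha += rng.normal(0, 0.1, size=alpha.shape)
    psi = np.full((K, F), 0.5 if spec.variant == "FMM2" else 0.0)
    sigma2 = np.clip(Y[:, ~bmask].var(axis=0), 1e-4, None)
    params = FMMParams(tau=tau, lam=lam, alpha=alpha, psi=psi, sigma2=sigma2,
                       pi=np.full(K, 1.0 / K))
    return params, resp


def count_parameters(model: str, K: int, F: int, n_binary: int = 50,
                     n_continuous: int = 4, covariate: bool = True) -> int:
    """Free-parameter counts under the identification conventions used here."""
    J = n_binary + n_continuous
    if model == "LCA":
        return n_binary * K + n_continuous * K + n_continuous + (K - 1)
    rot = F * (F - 1) // 2
    if model == "FA":
        return J + J * F - rot + n_continuous
    mix = 2 * (K - 1) if covariate else (K - 1)
    if model == "FMM1":
        if K == 1:
            return J + n_continuous
        return J + J * F - rot + max(F * (K - 2), 0) + n_continuous + mix
    if model == "FMM2":
        return J + (J * F - F - rot) + F * (K - 1) + K * F + n_continuous + mix
    raise ValueError(f"unknown model {model!r}")


# --------------------------------------------------------------------------
# fitting drivers
# --------------------------------------------------------------------------

def _em_fmm(Y, bmask, spec, code, params, resp, tol, max_iter):
    """One EM run from the given starting point. Returns (params, ll_trace, resp)."""
    n = Y.shape[0]
    K, F = spec.n_classes, spec.n_factors
    fmm2 = spec.variant == "FMM2"
    nodes, _ = (_factor_nodes(F, spec.variant) if fmm2
                else (np.zeros((1, F)), np.zeros(1)))
    trace = []
    update_lam = not (spec.variant == "FMM1" and K == 1)
    if not update_lam:
        params = replace(params, lam=np.zeros_like(params.lam),
                         alpha=np.zeros_like(params.alpha))
    ll_prev = -np.inf
    converged = False
    for it in range(max_iter):
        lj, H = _log_joint(Y, params, spec, code, bmask)  # (n, K, Q)
        ll = float(logsumexp(lj.reshape(n, -1), axis=1).sum())
        trace.append(ll)
        lpost = lj - logsumexp(lj.reshape(n, -1), axis=1)[:, None, None]
        post = np.exp(lpost)  # (n, K, Q)
        resp = post.sum(axis=2)
        if it > 0 and ll - ll_prev < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_prev = ll
        if np.any(resp.sum(axis=0) < 0.5):  # a class lost all its mass
            return params, np.asarray(trace), resp, False
        # aggregated sufficient statistics on the (K*Q) design
        W = post.reshape(n, -1)  # (n, M)
        N = W.sum(axis=0)
        S = Y.T @ W  # (J, M)
        cidx = np.flatnonzero(~bmask)
        SS = (Y[:, cidx] ** 2).T @ W  # (J_cont, M)
        Q = H.shape[1]
        # 1) membership model
        if spec.covariate_included and code is not None and K > 1:
            g0, g1 = m_step_multinomial(resp, code)
            params = replace(params, gamma0=g0, gamma1=g1, pi=None)
        else:
            params = replace(params, pi=resp.mean(axis=0),
                             gamma0=None, gamma1=None)
        # 2) measurement parameters
        params = _measurement_update(
            params, (N, S, SS), H.reshape(-1, F), bmask, update_lam=update_lam
        )
        # 3) class factor means / variances
        if update_lam:
            per_class = [
                (N.reshape(K, Q)[k], S.reshape(-1, K, Q)[:, k, :],
                 SS.reshape(-1, K, Q)[:, k, :])
                for k in range(K)
            ]
            params = _update_class_factors(params, per_class, nodes, bmask, fmm2)
            params = _renormalize(params, spec, resp.sum(axis=0))
    return params, np.asarray(trace), resp, converged


def _order_classes(params: FMMParams, resp: np.ndarray, code) -> tuple[FMMParams, np.ndarray]:
    """Relabel so the first factor mean is ascending (class 1 = lowest)."""
    order = np.argsort(params.alpha[:, 0])
    if np.array_equal(order, np.arange(len(order))):
        return params, resp
    params = replace(
        params,
        alpha=params.alpha[order],
        psi=params.psi[order],
        pi=params.pi[order] if params.pi is not None else None,
    )
    resp = resp[:, order]
    if params.gamma0 is not None and code is not None:
        g0, g1 = m_step_multinomial(resp, code)
        params = replace(params, gamma0=g0, gamma1=g1)
    return params, resp


def fit_fmm(
    data: ItemResponseDataset | np.ndarray,
    spec: FMMSpec,
    covariate: np.ndarray | None = None,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    warm_start: FMMFit | None = None,
) -> FMMFit:
    """Fit an FMM-1/FMM-2 by (generalized) EM with multiple restarts.

    The best converged restart by log-likelihood is kept and classes are
    relabeled so the factor means ascend. ``warm_start`` (e.g. an FMM-1 fit
    when fitting FMM-2 at the same size) is prepended as an extra restart.
    """
    Y, bmask, code = _prepare(data, spec, covariate)
    rng = np.random.default_rng(seed)
    best = None
    n_used = 0
    starts: list[tuple[FMMParams, np.ndarray]] = []
    if warm_start is not None:
        wp = warm_start.params
        psi0 = np.full((spec.n_classes, spec.n_factors), 1e-6)
        starts.append((replace(wp, psi=psi0), warm_start.responsibilities))
    for _ in range(restarts):
        starts.append(_initial_params(Y, bmask, spec, rng))
    for params0, resp0 in starts:
        n_used += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params, trace, resp, ok = _em_fmm(
                Y, bmask, spec, code, params0, resp0, tol, max_iter
            )
        if len(trace) == 0 or not np.isfinite(trace[-1]):
            continue
        if ok and (best is None or trace[-1] > best[1][-1]):
            best = (params, trace, resp)
    if best is None:
        raise ConvergenceError(
            f"no EM restart converged for {spec} after {n_used} starts"
        )
    params, trace, resp = best
    params, resp = _order_classes(params, resp, code)
    ll = float(trace[-1])
    p = count_parameters(spec.variant, spec.n_classes, spec.n_factors,
                         int(bmask.sum()), int((~bmask).sum()),
                         spec.covariate_included and code is not None)
    bic, aic = information_criteria(ll, p, Y.shape[0])
    return FMMFit(spec=spec, params=params, loglik=ll, n_params=p, bic=bic,
                  aic=aic, responsibilities=resp, converged=True,
                  n_iter=len(trace), n_restarts_used=n_used,
                  loglik_trace=trace, model=spec.variant)


def fit_fa(data, F: int = 1, seed: int = 0, tol: float = 1e-6,
           max_iter: int = 300) -> FMMFit:
    """One-class full-information factor analysis for the mixed item bank.

    The factor is standard normal; binary items are integrated by
    Gauss-Hermite quadrature. Returned as an FMMFit (K = 1) for the ladder.
    """
    if F < 1:
        raise ValueError("F must be >= 1")
    Y, bmask, _ = _prepare(data, None, None)
    rng = np.random.default_rng(seed)
    n, J = Y.shape
    nodes, logw = _factor_nodes(F, "FA")
    pbar = np.clip(Y[:, bmask].mean(axis=0), 0.02, 0.98)
    tau = np.zeros(J)
    tau[bmask] = np.log(pbar / (1 - pbar))
    tau[~bmask] = Y[:, ~bmask].mean(axis=0)
    lam = rng.uniform(0.2, 0.6, size=(J, F))
    sigma2 = np.clip(Y[:, ~bmask].var(axis=0), 1e-4, None)
    params = FMMParams(tau=tau, lam=lam, alpha=np.zeros((1, F)),
                       psi=np.ones((1, F)), sigma2=sigma2, pi=np.ones(1))
    trace = []
    ll_prev = -np.inf
    for it in range(max_iter):
        comp = _component_logpdf(Y, params.tau, params.lam, params.sigma2,
                                 nodes, bmask)
        lj = logw[None, :] + comp
        ll = float(logsumexp(lj, axis=1).sum())
        trace.append(ll)
        if it > 0 and ll - ll_prev < tol * (abs(ll) + 1.0):
            break
        ll_prev = ll
        post = np.exp(lj - logsumexp(lj, axis=1, keepdims=True))
        N = post.sum(axis=0)
        S = Y.T @ post
        cidx = np.flatnonzero(~bmask)
        SS = (Y[:, cidx] ** 2).T @ post
        params = _measurement_update(params, (N, S, SS), nodes, bmask)
        if not np.all(np.isfinite(params.lam)) or np.any(np.abs(params.lam) > 25):
            raise ConvergenceError("factor analysis diverged (Heywood-type)")
    p = count_parameters("FA", 1, F, int(bmask.sum()), int((~bmask).sum()))
    bic, aic = information_criteria(trace[-1], p, n)
    return FMMFit(
        spec=FMMSpec(1, F, "FMM2", covariate_included=False), params=params,
        loglik=float(trace[-1]), n_params=p, bic=bic, aic=aic,
        responsibilities=np.ones((n, 1)), converged=True, n_iter=len(trace),
        n_restarts_used=1, loglik_trace=np.asarray(trace), model="FA",
    )


def fit_lca(data, K: int, seed: int = 0, restarts: int = 5,
            tol: float = 1e-7, max_iter: int = 500) -> FMMFit:
    """Latent class / profile analysis baseline.

    Binary items are class-conditional Bernoulli; continuous items are
    class-conditional Gaussian with class-specific means and class-invariant
    variances, matching the error model the factor mixtures use so the
    ladder compares like with like.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    Y, bmask, _ = _prepare(data, None, None)
    n, J = Y.shape
    cidx = np.flatnonzero(~bmask)
    bidx = np.flatnonzero(bmask)
    rng = np.random.default_rng(seed)

    def run(resp):
        ll_prev, trace = -np.inf, []
        for it in range(max_iter):
            Nk = resp.sum(axis=0)
            if np.any(Nk < 0.5):
                return None
            pi = Nk / n
            P = np.clip((Y[:, bidx].T @ resp) / Nk, 1e-6, 1 - 1e-6)  # (Jb, K)
            mu = (Y[:, cidx].T @ resp) / Nk  # (Jc, K)
            # pooled within-class variance, shared across classes
            pooled = (
                ((Y[:, cidx] ** 2).T @ resp).sum(axis=1) / n
                - ((mu**2) * Nk[None, :]).sum(axis=1) / n
            )
            var = np.clip(np.tile(pooled[:, None], (1, K)), 1e-6, None)
            logf = Y[:, bidx] @ np.log(P) + (1 - Y[:, bidx]) @ np.log(1 - P)
            for c in range(len(cidx)):
                resid = Y[:, cidx[c]][:, None] - mu[c][None, :]
                logf += -0.5 * (resid**2 / var[c] + np.log(2 * np.pi * var[c]))
            lj = np.log(pi)[None, :] + logf
            ll = float(logsumexp(lj, axis=1).sum())
            trace.append(ll)
            resp = np.exp(lj - logsumexp(lj, axis=1, keepdims=True))
            if ll - ll_prev < tol * (abs(ll) + 1.0) and it > 0:
                break
            ll_prev = ll
        return pi, P, mu, var, resp, np.asarray(trace)

    from sklearn.cluster import KMeans

    best = None
    for r in range(max(restarts, 1)):
        if K == 1:
            resp = np.ones((n, 1))
        else:
            km = KMeans(n_clusters=K, n_init=2,
                        random_state=int(rng.integers(2**31 - 1)))
            hard = km.fit_predict(Y)
            resp = np.full((n, K), 0.05 / max(K - 1, 1))
            resp[np.arange(n), hard] = 0.95
            resp = resp + rng.uniform(0, 0.05 * (r > 0), size=resp.shape)
            resp /= resp.sum(axis=1, keepdims=True)
        out = run(resp)
        if out is None:
            continue
        if best is None or out[5][-1] > best[5][-1]:
            best = out
        if K == 1:
            break
    if best is None:
        raise ConvergenceError(f"all LCA restarts collapsed for K={K}")
    pi, P, mu, var, resp, trace = best
    # order classes by overall binary mean ascending for stable labels
    order = np.argsort(P.mean(axis=0))
    pi, P, mu, var, resp = pi[order], P[:, order], mu[:, order], var[:, order], resp[:, order]
    tau = np.zeros(J)
    lam = np.zeros((J, 1))
    tau[bidx] = np.log(P[:, 0] / (1 - P[:, 0]))
    tau[cidx] = mu[:, 0]
    params = FMMParams(tau=tau, lam=lam, alpha=np.zeros((K, 1)),
                       psi=np.zeros((K, 1)), sigma2=var.mean(axis=1), pi=pi)
    params.lca_item_probs = P  # class-conditional tables kept for inspection
    params.lca_means, params.lca_vars = mu, var
    p = count_parameters("LCA", K, 1, len(bidx), len(cidx))
    bic, aic = information_criteria(trace[-1], p, n)
    return FMMFit(
        spec=FMMSpec(K, 1, "FMM1", covariate_included=False), params=params,
        loglik=float(trace[-1]), n_params=p, bic=bic, aic=aic,
        responsibilities=resp, converged=True, n_iter=len(trace),
        n_restarts_used=restarts, loglik_trace=trace, model="LCA",
    )


def model_ladder(
    data,
    covariate: np.ndarray | None = None,
    class_grid: Sequence[int] = (1, 2, 3),
    factor_grid: Sequence[int] = (1, 2),
    seed: int = 0,
    restarts: int = 3,
) -> LadderResult:
    """The stepwise model comparison: LCA and FA baselines, then FMM grids.

    LCA is fitted over ``class_grid`` and FA over ``factor_grid``; their BIC
    optima bound the FMM grids (classes up to the LCA optimum, factors up to
    the FA optimum). All converged fits enter one table and the BIC minimizer
    wins. Non-converged cells are flagged and excluded from selection.
    """
    if not len(class_grid) or not len(factor_grid):
        raise ValueError("grids must be non-empty")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    row_fits: list[FMMFit | None] = []
    fits: dict = {}

    def record(name, K, F, fit, error=None):
        rows.append({
            "model": name, "n_classes": K, "n_factors": F,
            "loglik": fit.loglik if fit else np.nan,
            "n_params": fit.n_params if fit else np.nan,
            "bic": fit.bic if fit else np.nan,
            "aic": fit.aic if fit else np.nan,
            "converged": bool(fit), "error": error or "",
        })
        row_fits.append(fit)
        if fit:
            fits[(name, K, F)] = fit

    for K in class_grid:
        try:
            record("LCA", K, None, fit_lca(data, K, seed=int(rng.integers(2**31 - 1)),
                                           restarts=restarts))
        except ConvergenceError as exc:
            record("LCA", K, None, None, str(exc))
    for F in factor_grid:
        try:
            record("FA", None, F, fit_fa(data, F, seed=int(rng.integers(2**31 - 1))))
        except ConvergenceError as exc:
            record("FA", None, F, None, str(exc))

    lca_rows = [r for r in rows if r["model"] == "LCA" and r["converged"]]
    fa_rows = [r for r in rows if r["model"] == "FA" and r["converged"]]
    k_max = (min(rows_bic["n_classes"] for rows_bic in lca_rows
                 if rows_bic["bic"] == min(r["bic"] for r in lca_rows))
             if lca_rows else max(class_grid))
    f_max = (min(rows_bic["n_factors"] for rows_bic in fa_rows
                 if rows_bic["bic"] == min(r["bic"] for r in fa_rows))
             if fa_rows else max(factor_grid))
    k_grid = [k for k in class_grid if k <= max(k_max, 2)]
    f_grid = [f for f in factor_grid if f <= max(f_max, 1)]

    for variant in ("FMM1", "FMM2"):
        for K in k_grid:
            for F in f_grid:
                spec = FMMSpec(K, F, variant, covariate_included=True)
                warm = fits.get(("FMM1", K, F)) if variant == "FMM2" else None
                try:
                    fit = fit_fmm(data, spec, covariate=covariate,
                                  restarts=restarts,
                                  seed=int(rng.integers(2**31 - 1)),
                                  warm_start=warm)
                    record(variant, K, F, fit)
                except ConvergenceError as exc:
                    record(variant, K, F, None, str(exc))

    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        raise ConvergenceError("no model in the ladder converged")
    widx = int(ok["bic"].idxmin())
    return LadderResult(table=table, winner=row_fits[widx], fits=fits)


def align_alpha(
    params: FMMParams,
    true_loadings: np.ndarray,
    true_thresholds: np.ndarray,
    binary_mask: np.ndarray,
) -> np.ndarray:
    """Map estimated class factor means onto a generating truth's scale.

    The latent metric is identified only up to an affine transform
    eta -> a*eta + b; ``a`` and ``b`` are estimated by regressing the fitted
    loadings and threshold shifts on the true ones. Only binary items enter
    the regression: they follow the fitted measurement model exactly, whereas
    the continuous items are generated through squashing transforms the
    linear-Gaussian measurement part only approximates.
    """
    bm = np.asarray(binary_mask, bool)
    lam_t = np.asarray(true_loadings, float)[bm]
    tau_t = np.asarray(true_thresholds, float)[bm]
    lam_e = params.lam[bm, 0]
    tau_e = params.tau[bm]
    a = float(lam_t @ lam_e) / float(lam_t @ lam_t)
    b = float(lam_t @ (tau_e - tau_t)) / float(lam_t @ lam_t)
    return a * params.alpha[:, 0] + b


def expected_response_profiles(params: FMMParams, schema=None) -> np.ndarray:
    """(K, J) expected item responses per class from an FMM-1 fit.

    Binary items pass tau + lambda'alpha through the logistic link; the
    [0, 1] attention scores are clipped to their range and the nonnegative
    span score is floored at zero.
    """
    from .schema import default_schema

    schema = schema or default_schema()
    eta = params.tau[None, :] + params.alpha @ params.lam.T  # (K, J)
    out = np.empty_like(eta)
    if eta.shape[1] != schema.n_items:  # toy banks: treat every item as binary
        return expit(eta)
    for j, it in enumerate(schema.items):
        if it.scale == "binary":
            out[:, j] = expit(eta[:, j])
        elif it.scale == "unit_interval":
            out[:, j] = np.clip(eta[:, j], 0.0, 1.0)
        else:
            out[:, j] = np.maximum(eta[:, j], 0.0)
    return out
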