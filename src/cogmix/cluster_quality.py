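"""Crisp and fuzzy cluster validity indices.

Crisp indices (silhouette, Calinski-Harabasz, Davies-Bouldin) operate on a
point cloud and hard labels; fuzzy indices (Xie-Beni, fuzzy partition
coefficient, partition entropy) operate on an n × K membership matrix whose
rows sum to one. All distances are Euclidean. Degenerate geometry (zero
within-cluster scatter, coincident centroids) is reported through an
infinity sentinel rather than an exception so that a full report can always
be assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np

__all__ = [
    "silhouette",
    "calinski_harabasz",
    "davies_bouldin",
    "xie_beni",
    "fuzzy_partition_coefficient",
    "partition_entropy",
    "quality_report",
    "ClusterQualityReport",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (e.g. a single cluster)."""


def _check_labels(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("X and labels disagree on n")
    return X, labels


def _check_membership(U: np.ndarray) -> np.ndarray:
    U = np.asarray(U, dtype=float)
    if U.ndim != 2:
        raise ValueError("membership matrix must be 2-dimensional")
    if np.any(U < -1e-12) or np.any(U > 1 + 1e-12):
        raise ValueError("memberships must lie in [0, 1]")
    if not np.allclose(U.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("membership rows must sum to 1")
    return np.clip(U, 0.0, 1.0)


def silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width: (b - a) / max(a, b) per point.

    ``a`` is the mean distance to the point's own cluster (excluding itself),
    ``b`` the smallest mean distance to another cluster. Points in singleton
    clusters contribute 0 by convention.
    """
    X, labels = _check_labels(X, labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise UndefinedMetricError("silhouette needs at least 2 clusters")
    if X.shape[0] < 3:
        raise UndefinedMetricError("silhouette needs n >= 3")
    D = np.sqrt(np.maximum(
        ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1), 0.0))
    n, K = X.shape[0], len(uniq)
    counts = np.bincount(inv, minlength=K)
    # per-point summed distance to each cluster
    sums = np.zeros((n, K))
    for k in range(K):
        sums[:, k] = D[:, inv == k].sum(axis=1)
    own = counts[inv]
    s = np.zeros(n)
    nontrivial = own > 1
    a = np.where(nontrivial, sums[np.arange(n), inv] / np.maximum(own - 1, 1), 0.0)
    mean_other = sums / counts[None, :]
    mean_other[np.arange(n), inv] = np.inf
    b = mean_other.min(axis=1)
    denom = np.maximum(a, b)
    s[nontrivial] = ((b - a) / denom)[nontrivial]
    return float(s.mean())


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Variance-ratio criterion (B/(K-1)) / (W/(n-K)); higher is better."""
    X, labels = _check_labels(X, labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    n, K = X.shape[0], len(uniq)
    if not 2 <= K < n:
        raise UndefinedMetricError("requires 2 <= K < n")
    grand = X.mean(axis=0)
    B = W = 0.0
    for k in range(K):
        Xk = X[inv == k]
        ck = Xk.mean(axis=0)
        B += len(Xk) * float(((ck - grand) ** 2).sum())
        W += float(((Xk - ck) ** 2).sum())
    if W == 0.0:
        return float("inf")
    return (B / (K - 1)) / (W / (n - K))


def davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean over clusters of the worst (S_k + S_j) / ||c_k - c_j|| ratio."""
    X, labels = _check_labels(X, labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    K = len(uniq)
    if K < 2:
        raise UndefinedMetricError("requires K >= 2")
    centroids = np.stack([X[inv == k].mean(axis=0) for k in range(K)])
    S = np.array([
        float(np.sqrt(((X[inv == k] - centroids[k]) ** 2).sum(axis=1)).mean())
        for k in range(K)
    ])
    M = np.sqrt(((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(-1))
    if np.any((M + np.eye(K)) == 0.0):
        return float("inf")
    with np.errstate(divide="ignore"):
        R = (S[:, None] + S[None, :]) / np.where(M > 0, M, np.inf)
    np.fill_diagonal(R, -np.inf)
    return float(R.max(axis=1).mean())


def xie_beni(
    X: np.ndarray,
    U: np.ndarray,
    m: float = 2.0,
    centroids: np.ndarray | None = None,
) -> float:
    """Xie-Beni index: fuzzy within-compactness over minimum centroid
    separation; lower is better.

    Centroids default to the membership^m-weighted means; externally supplied
    centroids (e.g. a model's component means) may be passed instead.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    U = _check_membership(U)
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    n, K = U.shape
    Um = U ** m
    if centroids is None:
        denom = Um.sum(axis=0)
        if np.any(denom == 0):
            return float("inf")
        centroids = (Um.T @ X) / denom[:, None]
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)  # (n, K)
    numerator = float((Um * d2).sum())
    sep = ((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(sep, np.inf)
    min_sep = float(sep.min())
    if min_sep == 0.0:
        return float("inf")
    return numerator / (n * min_sep)


def fuzzy_partition_coefficient(U: np.ndarray) -> float:
    """Mean squared membership; 1 for a crisp partition, 1/K for uniform."""
    U = _check_membership(U)
    return float((U ** 2).sum() / U.shape[0])


def partition_entropy(U: np.ndarray) -> float:
    """Mean membership entropy (natural log); 0 crisp, ln K uniform."""
    U = _check_membership(U)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(U > 0, U * np.log(U), 0.0)
    return float(-terms.sum() / U.shape[0] + 0.0)


@dataclass
class ClusterQualityReport:
    """The index battery for one clustering solution in one feature space."""

    n: int
    n_clusters: int
    space: str
    silhouette: float | None = None
    calinski_harabasz: float | None = None
    davies_bouldin: float | None = None
    xie_beni: float | None = None
    fpc: float | None = None
    partition_entropy: float | None = None
    flags: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def quality_report(
    X: np.ndarray,
    labels: np.ndarray | None = None,
    U: np.ndarray | None = None,
    m: float = 2.0,
    space: str = "feature",
) -> ClusterQualityReport:
    """Assemble the full index battery.

    Crisp indices use ``labels`` (or the row-wise argmax of ``U`` when only
    memberships are given); fuzzy indices are included only when ``U`` is
    available. Undefined members are reported as flags, not raised.
    """
    if labels is None and U is None:
        raise ValueError("need labels or a membership matrix")
    if labels is None:
        labels = np.argmax(U, axis=1)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    report = ClusterQualityReport(
        n=X.shape[0], n_clusters=len(np.unique(labels)), space=space, flags={}
    )
    for name, fn in (
        ("silhouette", silhouette),
        ("calinski_harabasz", calinski_harabasz),
        ("davies_bouldin", davies_bouldin),
    ):
        try:
            setattr(report, name, fn(X, labels))
        except UndefinedMetricError as exc:
            report.flags[name] = str(exc)
    if U is not None:
        U = _check_membership(U)
        xb = xie_beni(X, U, m=m)
        if np.isinf(xb):
            report.flags["xie_beni"] = "coincident centroids"
        report.xie_beni = xb
        report.fpc = fuzzy_partition_coefficient(U)
        report.partition_entropy = partition_entropy(U)
    return report
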