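"""Feature-focused cluster interpretation.

Per-cluster item means are expressed as z-scores against the global item
statistics (sample SD, n-1 denominator), the unit in which cognitive
profiles are narrated: a cluster with z = +0.45 on a visuospatial item is
about half a global standard deviation above the sample average on that
task. Clusters below a minimum size (default 10) are excluded from
interpretation but retained in the counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ClusterProfile",
    "cluster_feature_zscores",
    "age_cluster_distribution",
    "filter_small_clusters",
]

#: |z| thresholds for the narrative bands (presentation only).
Z_BANDS = ((1.0, "severe"), (0.5, "moderate"), (0.2, "slight"))


def _band(z: float) -> str:
    for cut, name in Z_BANDS:
        if abs(z) >= cut:
            return name
    return "average"


@dataclass
class ClusterProfile:
    """Per-cluster sizes, item means, z-scores and band labels.

    ``zscores``/``means`` are DataFrames indexed by cluster label with one
    column per item; ``sizes`` maps cluster label to n. ``zero_variance``
    flags items whose global SD is zero (their z is defined as 0).
    """

    sizes: dict
    means: pd.DataFrame
    zscores: pd.DataFrame
    global_mean: pd.Series
    global_sd: pd.Series
    zero_variance: list = field(default_factory=list)
    min_n: int | None = None
    excluded: list = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return int(sum(self.sizes.values()))

    def bands(self) -> pd.DataFrame:
        return self.zscores.map(_band)

    def to_narrative(self) -> dict:
        """JSON-ready summary: per cluster, items grouped by band."""
        out = {}
        for cluster in self.zscores.index:
            z = self.zscores.loc[cluster]
            out[str(cluster)] = {
                "n": self.sizes[cluster],
                "bands": {
                    item: {"z": round(float(z[item]), 3), "band": _band(z[item])}
                    for item in z.index
                    if _band(z[item]) != "average"
                },
            }
        return out


def cluster_feature_zscores(data, labels: np.ndarray) -> ClusterProfile:
    """Per-cluster per-item means and z-scores against global statistics.

    ``data`` is an ItemResponseDataset or a DataFrame of item columns.
    z = (cluster mean - global mean) / global SD with the sample (n-1) SD;
    items with zero global variance get z = 0 and are flagged.
    """
    if hasattr(data, "to_frame"):
        frame = data.to_frame().drop(columns=["participant_id", "age"])
    else:
        frame = pd.DataFrame(data)
    labels = np.asarray(labels)
    if len(labels) != len(frame):
        raise ValueError("labels must align with rows")
    gmean = frame.mean(axis=0)
    gsd = frame.std(axis=0, ddof=1)
    zero_var = list(gmean.index[gsd == 0])
    safe_sd = gsd.replace(0.0, np.nan)
    uniq = np.unique(labels)
    sizes, mean_rows = {}, {}
    for k in uniq:
        mask = labels == k
        if not mask.any():
            warnings.warn(f"cluster {k} is empty; omitted")
            continue
        sizes[k] = int(mask.sum())
        mean_rows[k] = frame[mask].mean(axis=0)
    means = pd.DataFrame(mean_rows).T
    z = means.sub(gmean, axis=1).div(safe_sd, axis=1).fillna(0.0)
    return ClusterProfile(
        sizes=sizes, means=means, zscores=z,
        global_mean=gmean, global_sd=gsd, zero_variance=zero_var,
    )


def age_cluster_distribution(labels: np.ndarray, bin_index: np.ndarray) -> pd.DataFrame:
    """Proportion of each cluster within each age bin; rows (bins) sum to 1.

    Empty bins yield a zero row (flagged via the ``empty_bins`` attribute of
    the returned frame's ``attrs``).
    """
    labels = np.asarray(labels)
    bin_index = np.asarray(bin_index)
    if labels.shape != bin_index.shape:
        raise ValueError("labels and bin_index must align")
    clusters = np.unique(labels)
    bins = range(3)
    table = pd.DataFrame(0.0, index=list(bins), columns=list(clusters))
    empty = []
    for b in bins:
        mask = bin_index == b
        if not mask.any():
            empty.append(b)
            continue
        counts = pd.Series(labels[mask]).value_counts()
        table.loc[b, counts.index] = counts.values / mask.sum()
    table.index.name = "age_bin"
    table.attrs["empty_bins"] = empty
    return table


def filter_small_clusters(profile: ClusterProfile, min_n: int = 10) -> ClusterProfile:
    """Drop clusters with n < min_n from interpretation output.

    The threshold is inclusive: a cluster with exactly ``min_n`` members is
    retained. Sizes of excluded clusters stay in ``sizes`` so that totals are
    conserved; idempotent for a fixed threshold.
    """
    keep = [k for k in profile.zscores.index if profile.sizes[k] >= min_n]
    dropped = [k for k in profile.zscores.index if profile.sizes[k] < min_n]
    return replace(
        profile,
        means=profile.means.loc[keep],
        zscores=profile.zscores.loc[keep],
        min_n=min_n,
        excluded=sorted(set(profile.excluded) | set(dropped)),
    )
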