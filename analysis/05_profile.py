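#!/usr/bin/env python
"""Interpret the VAE clusters: z-score profiles and age-bin distributions.

For every hard-assigned cluster the per-item means are expressed as z-scores
against the global item statistics; clusters below 10 members are excluded
from interpretation (but kept in the counts). The age-bin-by-cluster table
shows how profile prevalence shifts across the three age groups.
"""

import json
from pathlib import Path

import pandas as pd

from cogmix import profiling as pf
from cogmix.pipeline import load_dataset
from cogmix.synthetic import bin_ages

OUT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch"
MIN_N = 10


def main() -> None:
    data = load_dataset(DATA / "multi_profile_data.csv")
    memb = pd.read_csv(DATA / "cgmvae_memberships.csv")
    labels = memb["hard"].to_numpy()

    profile = pf.cluster_feature_zscores(data, labels)
    profile.zscores.round(4).to_csv(OUT / "cluster_zscores.csv",
                                    index_label="cluster")
    kept = pf.filter_small_clusters(profile, min_n=MIN_N)
    (OUT / "cluster_narrative.json").write_text(
        json.dumps(kept.to_narrative(), indent=2))

    excluded = [f"{k} (n={profile.sizes[k]})" for k in kept.excluded]
    print(f"clusters: {len(profile.sizes)} total, "
          f"{len(kept.zscores)} with n >= {MIN_N}"
          + (f"; excluded: {', '.join(excluded)}" if excluded else ""))

    bins, _ = bin_ages(data.ages)
    table = pf.age_cluster_distribution(labels, bins)
    table.round(4).to_csv(OUT / "age_by_cluster.csv")
    print("\nage-bin x cluster proportions:")
    print(table.round(3).to_string())

    for k in kept.zscores.index:
        z = kept.zscores.loc[k]
        hi, lo = z.idxmax(), z.idxmin()
        print(f"cluster {k} (n={kept.sizes[k]}): strongest {hi} "
              f"(z={z[hi]:+.2f}), weakest {lo} (z={z[lo]:+.2f})")


if __name__ == "__main__":
    main()
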