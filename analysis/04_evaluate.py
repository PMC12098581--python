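#!/usr/bin/env python
"""Score both clustering solutions with the validity-index battery.

The two-class EM solution is evaluated in its latent factor space (posterior
expected factor scores); the VAE solution in its latent embedding, with the
fuzzy indices computed on the membership matrix. The contrast mirrors the
methodological trade-off: few crisp classes versus many overlapping
profiles.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cogmix import cluster_quality as cq

OUT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    factor = pd.read_csv(DATA / "fmm_factor_scores.csv").to_numpy()
    resp = pd.read_csv(DATA / "fmm_responsibilities.csv").to_numpy()
    fmm_report = cq.quality_report(factor, labels=resp.argmax(axis=1),
                                   space="fmm_factor")

    memb = pd.read_csv(DATA / "cgmvae_memberships.csv")
    U = memb[[c for c in memb.columns if c.startswith("component_")]].to_numpy()
    emb = pd.read_csv(DATA / "cgmvae_embeddings.csv")
    X = emb[[c for c in emb.columns if c != "participant_id"]].to_numpy()
    cg_report = cq.quality_report(X, U=U, space="cgmvae_latent")

    both = {"fmm": fmm_report.to_dict(), "cgmvae": cg_report.to_dict()}
    (OUT / "cluster_quality.json").write_text(json.dumps(both, indent=2))

    rows = []
    for name, rep in (("FMM", fmm_report), ("CGMVAE", cg_report)):
        rows.append({
            "solution": name, "space": rep.space, "K": rep.n_clusters,
            "silhouette": rep.silhouette,
            "calinski_harabasz": rep.calinski_harabasz,
            "davies_bouldin": rep.davies_bouldin,
            "xie_beni": rep.xie_beni, "fpc": rep.fpc,
            "partition_entropy": rep.partition_entropy,
        })
    table = pd.DataFrame(rows)
    print(table.round(3).to_string(index=False))
    crisper = "FMM" if fmm_report.silhouette > (cg_report.silhouette or -1) else "CGMVAE"
    print(f"\nsharper separation: {crisper} "
          f"(silhouette {fmm_report.silhouette:.3f} vs "
          f"{cg_report.silhouette:.3f})")


if __name__ == "__main__":
    main()
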