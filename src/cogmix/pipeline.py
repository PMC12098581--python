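"""End-to-end orchestration: simulate -> fit both tracks -> evaluate -> profile.

The pipeline is a pure function of its configuration and seeds: every stage
writes a machine-readable artifact (CSV tables, JSON summaries) and the final
report references only numbers present in those artifacts.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cgmvae as cg
from . import cluster_quality as cq
from . import fmm as fm
from . import profiling as pf
from .schema import ItemResponseDataset, SchemaError, default_schema
from .synthetic import AgeModel, bin_ages, default_fmm_truth, simulate_fmm1

__all__ = ["PipelineConfig", "ComparisonReport", "load_dataset", "run_compare",
           "save_report", "render_summary"]


def load_dataset(path) -> ItemResponseDataset:
    """Read and validate a response CSV against the 54-item schema.

    Raises :class:`cogmix.schema.SchemaError` naming the offending column on
    any count, type or range violation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input dataset not found: {path}")
    return ItemResponseDataset.from_csv(path)


@dataclass
class PipelineConfig:
    """Configuration for a full comparison run."""

    n: int = 1000
    seed: int = 0
    data_path: str | None = None  # if given, load instead of simulating
    class_grid: tuple[int, ...] = (1, 2, 3)
    factor_grid: tuple[int, ...] = (1,)
    ladder_restarts: int = 3
    cgmvae: cg.CGMVAEConfig = field(default_factory=lambda: cg.CGMVAEConfig(
        latent_dim=8, n_components=4, hidden_dim=64, epochs=30))
    min_cluster_n: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cg_cfg = cg.CGMVAEConfig(**raw.pop("cgmvae", {}))
        for key in ("class_grid", "factor_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(cgmvae=cg_cfg, **raw)

    def to_yaml(self, path) -> None:
        import yaml
        from dataclasses import asdict

        payload = asdict(self)
        payload["class_grid"] = list(self.class_grid)
        payload["factor_grid"] = list(self.factor_grid)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class ComparisonReport:
    config: dict
    ladder: pd.DataFrame
    fmm_summary: dict
    cgmvae_summary: dict
    fmm_quality: cq.ClusterQualityReport
    cgmvae_quality: cq.ClusterQualityReport
    profile_narrative: dict
    age_distribution: pd.DataFrame
    failures: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)


def run_compare(config: PipelineConfig, outdir=None) -> ComparisonReport:
    """Execute the full two-track comparison; optionally write stage artifacts."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    failures, timings = {}, {}

    t0 = time.perf_counter()
    if config.data_path:
        data = load_dataset(config.data_path)
    else:
        data = simulate_fmm1(config.n, default_fmm_truth(), AgeModel(),
                             seed=int(rng.integers(2**31 - 1)))
    if out is not None:
        data.to_csv(out / "data.csv", labels_path=out / "true_labels.csv")
    bin_index, code = bin_ages(data.ages)
    timings["data"] = time.perf_counter() - t0

    # --- FMM track -------------------------------------------------------
    t0 = time.perf_counter()
    ladder = fm.model_ladder(
        data, covariate=code, class_grid=config.class_grid,
        factor_grid=config.factor_grid, seed=int(rng.integers(2**31 - 1)),
        restarts=config.ladder_restarts,
    )
    win = ladder.winner
    resp = win.responsibilities
    fmm_labels = resp.argmax(axis=1)
    # latent space for quality metrics: posterior expected factor score
    factor_space = resp @ win.params.alpha
    ors = {}
    if win.params.gamma0 is not None:
        for k, (g0, g1) in enumerate(zip(win.params.gamma0, win.params.gamma1)):
            orr, pct = fm.odds_ratio_from_coefficient(float(g1))
            ors[f"class{k + 1}_vs_ref"] = {
                "gamma0": float(g0), "gamma1": float(g1),
                "odds_ratio": orr, "percent_change": pct,
            }
    fmm_summary = {
        "model": win.model, "n_classes": win.spec.n_classes,
        "n_factors": win.spec.n_factors, "bic": win.bic, "aic": win.aic,
        "loglik": win.loglik,
        "class_proportions": resp.mean(axis=0).tolist(),
        "alpha": win.params.alpha[:, 0].tolist(),
        "odds_ratios": ors,
    }
    timings["fmm"] = time.perf_counter() - t0
    if out is not None:
        ladder.to_csv(out / "ladder.csv")
        (out / "fmm_winner.json").write_text(json.dumps(fmm_summary, indent=2))

    # --- CGMVAE track ----------------------------------------------------
    t0 = time.perf_counter()
    cgmvae_summary, cg_labels, U, embedding = {}, None, None, None
    try:
        cfg = config.cgmvae
        cfg = cg.replace_config(cfg, seed=int(rng.integers(2**31 - 1)))
        state, history = cg.train(data, cfg)
        U = cg.membership(data, state).memberships
        cg_labels = U.argmax(axis=1)
        embedding = cg.latent_embedding(data, state)
        cgmvae_summary = {
            "epochs_run": int(history["epoch"].iloc[-1]) + 1,
            "best_val_loss": float(history["val_total"].min()),
            "final_train_loss": float(history["train_total"].iloc[-1]),
            "config": cg.config_to_dict(cfg),
        }
        if out is not None:
            history.to_csv(out / "cgmvae_history.csv", index=False)
            pd.DataFrame(U).to_csv(out / "cgmvae_memberships.csv", index=False)
    except Exception as exc:  # stage failure -> partial report
        failures["cgmvae"] = repr(exc)
    timings["cgmvae"] = time.perf_counter() - t0

    # --- quality + profiling ---------------------------------------------
    fmm_quality = cq.quality_report(factor_space, labels=fmm_labels,
                                    space="fmm_factor")
    if cg_labels is not None:
        cg_quality = cq.quality_report(embedding, U=U, space="cgmvae_latent")
        profile_labels = cg_labels
    else:
        cg_quality = cq.ClusterQualityReport(n=data.n, n_clusters=0,
                                             space="cgmvae_latent",
                                             flags={"train": "failed"})
        profile_labels = fmm_labels
    profile = pf.cluster_feature_zscores(data, profile_labels)
    profile = pf.filter_small_clusters(profile, min_n=config.min_cluster_n)
    age_table = pf.age_cluster_distribution(profile_labels, bin_index)
    if out is not None:
        profile.zscores.to_csv(out / "cluster_zscores.csv")
        age_table.to_csv(out / "age_by_cluster.csv")

    report = ComparisonReport(
        config={"n": config.n, "seed": config.seed,
                "class_grid": list(config.class_grid),
                "factor_grid": list(config.factor_grid)},
        ladder=ladder.table, fmm_summary=fmm_summary,
        cgmvae_summary=cgmvae_summary, fmm_quality=fmm_quality,
        cgmvae_quality=cg_quality, profile_narrative=profile.to_narrative(),
        age_distribution=age_table, failures=failures, timings=timings,
    )
    if out is not None:
        save_report(report, out / "report.json")
    return report


def save_report(report: ComparisonReport, path) -> None:
    payload = {
        "config": report.config,
        "ladder": report.ladder.to_dict(orient="records"),
        "fmm": report.fmm_summary,
        "cgmvae": report.cgmvae_summary,
        "fmm_quality": report.fmm_quality.to_dict(),
        "cgmvae_quality": report.cgmvae_quality.to_dict(),
        "profiles": report.profile_narrative,
        "age_distribution": report.age_distribution.to_dict(orient="index"),
        "failures": report.failures,
        "timings": report.timings,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)


def load_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def render_summary(report: ComparisonReport) -> str:
    """Human-readable digest of one comparison run."""
    lines = ["=== cognitive-profile clustering comparison ==="]
    w = report.fmm_summary
    lines.append(
        f"ladder winner: {w['model']} K={w['n_classes']} F={w['n_factors']} "
        f"(BIC={w['bic']:.2f}, AIC={w['aic']:.2f})"
    )
    lines.append("class proportions: "
                 + ", ".join(f"{p:.3f}" for p in w["class_proportions"]))
    for name, o in w["odds_ratios"].items():
        lines.append(
            f"age covariate {name}: gamma1={o['gamma1']:.3f} "
            f"OR={o['odds_ratio']:.3f} ({o['percent_change']:+.1f}% odds)"
        )
    for label, q in (("FMM", report.fmm_quality), ("CGMVAE", report.cgmvae_quality)):
        lines.append(
            f"{label} quality [{q.space}]: Silhouette={_fmt(q.silhouette)} "
            f"Calinski-Harabasz={_fmt(q.calinski_harabasz)} "
            f"Davies-Bouldin={_fmt(q.davies_bouldin)} "
            f"Xie-Beni={_fmt(q.xie_beni)} FPC={_fmt(q.fpc)} "
            f"partition entropy={_fmt(q.partition_entropy)}"
        )
    for stage, err in report.failures.items():
        lines.append(f"stage {stage}: FAILED ({err})")
    return "\n".join(lines)


def _fmt(x) -> str:
    return "n/a" if x is None else f"{x:.3f}"
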