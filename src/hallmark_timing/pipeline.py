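"""File-level orchestration: YAML/dataclass config -> tables + figures.

``run_pipeline`` reads the input tables, fits :class:`HallmarkTimingModel`,
writes every result table plus a JSON manifest (versions, seed, attrition
counts at every filter, output paths), and optionally renders the report
figures.  Figures are derived from the tables; the tables are the contract.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import __version__
from .io import (
    read_exposure_matrix,
    read_feature_table,
    read_hallmark_map,
    read_mutation_table,
    read_signature_catalog,
)
from .model import HallmarkTimingModel, HallmarkTimingResults

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    mutations: str
    hallmark_map: str
    out_dir: str
    catalog: str | None = None
    cn_exposures: str | None = None
    features: str | None = None
    fasta: str | None = None
    k: int | str = "auto"
    seed: int = 123
    min_mutations: int = 50
    trim: float = 0.06
    R: int = 1000
    alpha: float = 0.05
    impute: bool = False
    render: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for attr in ("mutations", "hallmark_map", "catalog", "cn_exposures",
                     "features", "fasta"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis from files; returns the run manifest."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "read_inputs"
    try:
        mutations = read_mutation_table(config.mutations, strict=False)
        hm = read_hallmark_map(config.hallmark_map)
        catalog = read_signature_catalog(config.catalog) if config.catalog else None
        cn = (read_exposure_matrix(config.cn_exposures, kind="CN")
              if config.cn_exposures else None)
        features = read_feature_table(config.features) if config.features else None
        if config.fasta:
            from .signatures import resolve_contexts
            stage = "resolve_contexts"
            mutations = resolve_contexts(mutations, config.fasta)
        stage = "fit"
        model = HallmarkTimingModel(
            mutations, hm, catalog=catalog, cn_exposures=cn, features=features,
            impute=config.impute, min_mutations=config.min_mutations,
            trim=config.trim, R=config.R, alpha=config.alpha,
        )
        results = model.fit(k=config.k, seed=config.seed)
        stage = "write_tables"
        paths = results.save_tables(outdir)
        if config.render:
            stage = "render_reports"
            paths.update(render_reports(results, outdir, alpha=config.alpha))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "k": results.k,
        "counts": results.counts,
        "cluster_sizes": results.cluster_sizes,
        "average_silhouette": results.silhouette_avg,
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    (outdir / "summary.txt").write_text(results.summary() + "\n")
    return manifest


# ---------------------------------------------------------------------------
# report figures
# ---------------------------------------------------------------------------

_COLORS = {"EGI": "#1b1b1b", "LGI": "#8a8a8a", "none": "#c0392b"}


def significant_set(rows, alpha: float = 0.05) -> set[str]:
    """Features/signatures whose adjusted p falls below alpha."""
    return {r.feature for r in rows if np.isfinite(r.p_adj) and r.p_adj < alpha}


def render_reports(
    results: HallmarkTimingResults, outdir: str | Path, alpha: float = 0.05
) -> dict[str, Path]:
    """Figure-equivalent report files derived from the result tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # elbow curve
    fig, ax = plt.subplots(figsize=(5, 4))
    ks = [k for k, _ in results.wss]
    ws = [w for _, w in results.wss]
    ax.plot(ks, ws, "o-")
    ax.axvline(results.k, color="red", linestyle="--", label=f"k={results.k}")
    ax.set_xlabel("k")
    ax.set_ylabel("total within-cluster SS")
    ax.legend()
    paths["fig_elbow"] = outdir / "fig_elbow.png"
    fig.savefig(paths["fig_elbow"], dpi=120, bbox_inches="tight")
    plt.close(fig)

    # PCA biplot colored by cluster
    lm = results.label_map
    fig, ax = plt.subplots(figsize=(5, 4))
    for grp in ("EGI", "LGI"):
        sel = [s for s in results.pca.scores.index if lm.get(s) == grp]
        ax.scatter(results.pca.scores.loc[sel, "PC1"],
                   results.pca.scores.loc[sel, "PC2"],
                   s=8, alpha=0.6, label=grp, color=_COLORS[grp])
    scale = float(np.abs(results.pca.scores[["PC1", "PC2"]].to_numpy()).max())
    for hm, row in results.pca.loadings.iterrows():
        ax.annotate(hm, (row["PC1"] * scale, row["PC2"] * scale), fontsize=6)
        ax.arrow(0, 0, row["PC1"] * scale * 0.8, row["PC2"] * scale * 0.8,
                 alpha=0.3, width=1e-4)
    ax.set_xlabel(f"PC1 ({results.pca.var_explained[0]:.0%})")
    ax.set_ylabel(f"PC2 ({results.pca.var_explained[1]:.0%})")
    ax.legend()
    paths["fig_pca"] = outdir / "fig_pca.png"
    fig.savefig(paths["fig_pca"], dpi=120, bbox_inches="tight")
    plt.close(fig)

    # rank-ordered hallmark VAF curves with standard-error bars per cluster
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, grp in zip(axes, ("EGI", "LGI")):
        sel = [s for s in results.matrix.index if lm.get(s) == grp]
        sub = results.matrix.loc[sel]
        means = sub.mean(axis=0).sort_values(ascending=False)
        sems = sub.std(axis=0, ddof=1) / np.sqrt(len(sub))
        ax.errorbar(range(1, len(means) + 1), means.to_numpy(),
                    yerr=sems.loc[means.index].to_numpy(), fmt="o-", capsize=3)
        ax.set_xticks(range(1, len(means) + 1))
        ax.set_xticklabels(means.index, rotation=90, fontsize=6)
        ax.set_title(grp)
        ax.set_ylabel("mean VAF")
    paths["fig_hallmark_rank"] = outdir / "fig_hallmark_rank.png"
    fig.savefig(paths["fig_hallmark_rank"], dpi=120, bbox_inches="tight")
    plt.close(fig)

    # dominant-signature count histograms with significance asterisks
    for kind, dom, rows in (("cn", results.cn_dominant, results.cn_contingency),
                            ("sbs", results.sbs_dominant, results.sbs_contingency)):
        if not dom:
            continue
        sig_set = significant_set(rows, alpha)
        sigs = sorted(set(dom.values()))
        counts = {grp: [sum(1 for s, g in dom.items() if g == sig and lm.get(s) == grp)
                        for sig in sigs] for grp in ("EGI", "LGI")}
        x = np.arange(len(sigs))
        fig, ax = plt.subplots(figsize=(max(4, len(sigs)), 4))
        ax.bar(x - 0.2, counts["EGI"], width=0.4, label="EGI", color=_COLORS["EGI"])
        ax.bar(x + 0.2, counts["LGI"], width=0.4, label="LGI", color=_COLORS["LGI"])
        for i, sig in enumerate(sigs):
            if sig in sig_set:
                ax.annotate("*", (i, max(counts["EGI"][i], counts["LGI"][i])),
                            ha="center", fontsize=14)
        ax.set_xticks(x)
        ax.set_xticklabels(sigs, rotation=45, ha="right")
        ax.set_ylabel("patients with dominant signature")
        ax.legend()
        paths[f"fig_{kind}_dominant"] = outdir / f"fig_{kind}_dominant.png"
        fig.savefig(paths[f"fig_{kind}_dominant"], dpi=120, bbox_inches="tight")
        plt.close(fig)

    # forest plot of feature odds ratios
    fig, ax = plt.subplots(figsize=(6, max(2, 0.4 * len(results.feature_forest))))
    if results.feature_forest:
        ys = np.arange(len(results.feature_forest))
        for y, r in zip(ys, results.feature_forest):
            color = _COLORS[r.direction]
            est = r.estimate if np.isfinite(r.estimate) and r.estimate > 0 else np.nan
            lo = max(r.ci_lo, 1e-6) if np.isfinite(r.ci_lo) else np.nan
            hi = r.ci_hi if np.isfinite(r.ci_hi) else np.nan
            if np.isfinite(est):
                ax.plot([lo, hi], [y, y], color=color)
                ax.plot([est], [y], "o", color=color)
        ax.axvline(1.0, color="red", linestyle="--")
        ax.set_yticks(ys)
        ax.set_yticklabels([r.feature for r in results.feature_forest], fontsize=7)
        ax.set_xscale("log")
        ax.set_xlabel("odds ratio (LGI vs EGI)")
    else:
        ax.text(0.5, 0.5, "no association results", ha="center", va="center")
        ax.set_axis_off()
    paths["fig_forest"] = outdir / "fig_forest.png"
    fig.savefig(paths["fig_forest"], dpi=120, bbox_inches="tight")
    plt.close(fig)
    return paths
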