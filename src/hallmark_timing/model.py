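"""Model/results surface tying the whole analysis together.

``HallmarkTimingModel`` is built from a cohort's tables (mutations +
hallmark map, and optionally an SBS reference catalog, a CN exposure matrix
and a per-patient feature table); ``fit()`` runs profiling, clustering,
signature attribution and every association statistic, returning a
``HallmarkTimingResults`` whose attributes carry the estimates and whose
``summary()`` prints the headline tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import signatures as sigmod
from . import stats as statsmod
from . import timing
from .io import (
    AssociationResult,
    ExposureMatrix,
    FeatureTable,
    HallmarkMap,
    MutationRecord,
    SignatureCatalog,
    association_frame,
    write_matrix,
)


@dataclass
class HallmarkTimingResults:
    """Everything the fitted pipeline produced, plus bookkeeping counts."""

    model: "HallmarkTimingModel"
    profiles: list[timing.HallmarkProfile]
    matrix: pd.DataFrame
    pca: timing.PcaResult
    wss: list[tuple[int, float]]
    k: int
    assignments: pd.Series
    silhouette: pd.Series | None
    silhouette_avg: float
    labels: list[timing.ClusterLabel]
    label_margin: float
    hallmark_tests: list[AssociationResult]
    spectra: list[sigmod.Sbs96Spectrum] = field(default_factory=list)
    low_mutation_excluded: list[str] = field(default_factory=list)
    sbs_weights: list[sigmod.SignatureWeights] = field(default_factory=list)
    sbs_dominant: dict[str, str] = field(default_factory=dict)
    cn_dominant: dict[str, str] = field(default_factory=dict)
    sbs_contingency: list[AssociationResult] = field(default_factory=list)
    cn_contingency: list[AssociationResult] = field(default_factory=list)
    sbs_bootstrap: list[statsmod.BootstrapComparison] = field(default_factory=list)
    cn_bootstrap: list[statsmod.BootstrapComparison] = field(default_factory=list)
    feature_forest: list[AssociationResult] = field(default_factory=list)
    correlation: list[AssociationResult] = field(default_factory=list)
    correlation_scatter: pd.DataFrame = field(default_factory=pd.DataFrame)
    counts: dict[str, int] = field(default_factory=dict)

    # -- convenience views -------------------------------------------------

    @property
    def label_map(self) -> dict[str, str]:
        return {l.sample_id: l.label for l in self.labels}

    @property
    def cluster_sizes(self) -> dict[str, int]:
        sizes = {"EGI": 0, "LGI": 0}
        for l in self.labels:
            sizes[l.label] += 1
        return sizes

    def bootstrap_frame(self, kind: str = "CN") -> pd.DataFrame:
        comps = self.cn_bootstrap if kind == "CN" else self.sbs_bootstrap
        return pd.DataFrame([
            {
                "signature": c.signature,
                "observed_egi": c.observed_egi,
                "observed_lgi": c.observed_lgi,
                "ad_statistic": c.ad_statistic,
                "ad_p": c.ad_p,
                "ad_p_adj": c.ad_p_adj,
                "cohen_d": c.cohen_d,
                "d_ci_lo": c.d_ci[0],
                "d_ci_hi": c.d_ci[1],
                "d_bin": c.d_bin,
                "degenerate": c.degenerate,
            }
            for c in comps
        ])

    def summary(self) -> str:
        """Human-readable run summary (cluster sizes, QC, top associations)."""
        sizes = self.cluster_sizes
        lines = [
            "Hallmark genome-instability timing — fit summary",
            "=" * 52,
            f"samples clustered        : {len(self.labels)}"
            f"  (EGI {sizes['EGI']} / LGI {sizes['LGI']})",
            f"k (clusters)             : {self.k}",
            f"average silhouette width : {self.silhouette_avg:.3f}",
            f"GI mean-rank margin      : {self.label_margin:.2f}",
        ]
        if self.counts:
            lines.append(f"bookkeeping              : {self.counts}")
        if self.hallmark_tests:
            lines.append("")
            lines.append("Per-hallmark VAF comparison (Mann-Whitney, BH):")
            for r in self.hallmark_tests:
                lines.append(
                    f"  {r.feature:<22} dVAF(LGI-EGI)={r.estimate:+.4f}"
                    f"  p_adj={r.p_adj:.3g}  [{r.direction}]")
        for tag, rows in (("CN", self.cn_contingency), ("SBS", self.sbs_contingency)):
            if rows:
                lines.append("")
                lines.append(f"{tag} dominant-signature enrichment (contingency, BH):")
                for r in rows:
                    lines.append(
                        f"  {r.feature:<10} dfrac(EGI-LGI)={r.estimate:+.4f}"
                        f"  p_adj={r.p_adj:.3g}  [{r.direction}]")
        if self.feature_forest:
            lines.append("")
            lines.append("Feature enrichment (logistic OR, Bonferroni):")
            for r in self.feature_forest:
                ci = f"[{r.ci_lo:.3g}, {r.ci_hi:.3g}]"
                lines.append(
                    f"  {r.feature:<22} OR={r.estimate:.3g} {ci}"
                    f"  p_adj={r.p_adj:.3g}  [{r.direction}]")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save_tables(self, outdir: str | Path) -> dict[str, Path]:
        """Write every result table as TSV; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def put(name: str, df: pd.DataFrame, index_label: str | None = None):
            p = outdir / f"{name}.tsv"
            if index_label is not None:
                write_matrix(df, p, index_label=index_label)
            else:
                df.to_csv(p, sep="\t", index=False, float_format="%.17g")
            paths[name] = p

        put("profiles", self.matrix, index_label="sample_id")
        ranks = pd.DataFrame.from_dict(
            {p.sample_id: p.ranks for p in self.profiles}, orient="index"
        ).reindex(self.matrix.index)
        put("ranks", ranks, index_label="sample_id")
        put("pca_scores", self.pca.scores, index_label="sample_id")
        put("pca_loadings", self.pca.loadings, index_label="hallmark")
        put("wss_curve", pd.DataFrame(self.wss, columns=["k", "wss"]))
        lab = pd.DataFrame([
            {"sample_id": l.sample_id, "cluster_index": l.cluster_index,
             "label": l.label, "silhouette": l.silhouette}
            for l in self.labels
        ])
        put("labels", lab)
        put("hallmark_vaf_tests", association_frame(self.hallmark_tests))
        if self.spectra:
            spec = pd.DataFrame(
                {s.sample_id: s.counts for s in self.spectra},
                index=list(sigmod.SBS96_CHANNELS),
            ).T
            put("sbs_spectra", spec, index_label="sample_id")
        if self.sbs_weights:
            sig_names = list(self.model.catalog.signatures)
            put("sbs_weights", sigmod.weights_frame(self.sbs_weights, sig_names),
                index_label="sample_id")
        for name, dom in (("sbs_dominant", self.sbs_dominant),
                          ("cn_dominant", self.cn_dominant)):
            if dom:
                put(name, pd.DataFrame(
                    sorted(dom.items()), columns=["sample_id", "signature"]))
        for name, rows in (("sbs_contingency", self.sbs_contingency),
                           ("cn_contingency", self.cn_contingency),
                           ("feature_forest", self.feature_forest),
                           ("substitution_vaf_correlation", self.correlation)):
            if rows:
                put(name, association_frame(rows))
        for kind, comps in (("cn", self.cn_bootstrap), ("sbs", self.sbs_bootstrap)):
            if comps:
                put(f"{kind}_bootstrap", self.bootstrap_frame(kind.upper()))
        if len(self.correlation_scatter):
            put("substitution_vaf_scatter", self.correlation_scatter)
        return paths


class HallmarkTimingModel:
    """Two-cluster hallmark-timing model of a tumor cohort.

    Parameters
    ----------
    mutations : list of MutationRecord
        Somatic variants with VAF (and trinucleotide context for the
        signature stage).
    hallmark_map : HallmarkMap
        Gene -> hallmark assignment.
    catalog : SignatureCatalog, optional
        SBS reference spectra for the refitting stage.
    cn_exposures : ExposureMatrix, optional
        Per-patient CN signature exposures (dominant rule applied here).
    features : FeatureTable, optional
        Immune/stemness features for the logistic forest.
    impute : bool
        Fill missing hallmarks with the patient's overall mean VAF rather
        than dropping the patient from clustering.
    """

    def __init__(
        self,
        mutations: list[MutationRecord],
        hallmark_map: HallmarkMap,
        catalog: SignatureCatalog | None = None,
        cn_exposures: ExposureMatrix | None = None,
        features: FeatureTable | None = None,
        *,
        impute: bool = False,
        min_mutations: int = sigmod.MIN_MUTATIONS,
        trim: float = 0.06,
        fit_tol: float = 1e-3,
        R: int = 1000,
        alpha: float = 0.05,
    ) -> None:
        self.mutations = mutations
        self.hallmark_map = hallmark_map
        self.catalog = catalog
        self.cn_exposures = cn_exposures
        self.features = features
        self.impute = impute
        self.min_mutations = min_mutations
        self.trim = trim
        self.fit_tol = fit_tol
        self.R = R
        self.alpha = alpha

    @classmethod
    def from_cohort(cls, cohort: Any, **kwargs) -> "HallmarkTimingModel":
        """Build from a :class:`~hallmark_timing.simulate.SyntheticCohort`."""
        return cls(
            mutations=cohort.mutations,
            hallmark_map=cohort.hallmark_map,
            catalog=cohort.catalog,
            cn_exposures=cohort.cn_exposures,
            features=cohort.features,
            **kwargs,
        )

    def fit(
        self,
        k: int | str = "auto",
        seed: int = 123,
        k_max: int = 8,
        n_init: int = 25,
    ) -> HallmarkTimingResults:
        """Run the full analysis; see module docstring for the stages."""
        profiles = timing.compute_hallmark_profiles(
            self.mutations, self.hallmark_map, impute=self.impute)
        for p in profiles:
            timing.rank_hallmarks(p)
        matrix = timing.profile_matrix(profiles, require_complete=True)
        counts = {
            "samples_with_mutations": len(profiles),
            "samples_clustered": len(matrix),
            "samples_dropped_missing_hallmarks": len(profiles) - len(matrix),
        }
        pca = timing.run_pca(matrix)
        curve = timing.wss_curve(pca.scores, 1, min(k_max, len(matrix) - 1),
                                 seed=seed, n_init=n_init)
        chosen_k = timing.select_k_elbow(curve) if k == "auto" else int(k)
        assignments = timing.kmeans_assign(pca.scores, chosen_k, seed=seed, n_init=n_init)
        sil, sil_avg = (None, float("nan"))
        if chosen_k >= 2:
            sil, sil_avg = timing.silhouette_widths(pca.scores, assignments)
        if chosen_k != 2:
            raise ValueError(
                f"EGI/LGI labelling requires k=2 (got k={chosen_k}); "
                "re-run with k=2 or inspect the WSS curve")
        labels, margin = timing.label_egi_lgi(assignments, profiles, sil)
        label_map = {l.sample_id: l.label for l in labels}
        hallmark_tests = timing.compare_hallmark_vaf(profiles, labels)

        res = HallmarkTimingResults(
            model=self, profiles=profiles, matrix=matrix, pca=pca, wss=curve,
            k=chosen_k, assignments=assignments, silhouette=sil,
            silhouette_avg=sil_avg, labels=labels, label_margin=margin,
            hallmark_tests=hallmark_tests, counts=counts,
        )

        if self.catalog is not None:
            spectra, _rej = sigmod.build_spectra(self.mutations)
            retained, excluded = sigmod.apply_min_mutation_filter(
                spectra, self.min_mutations)
            retained = [s for s in retained if s.sample_id in label_map]
            if not retained:
                raise RuntimeError(
                    "signature stage: every sample fell below the "
                    f"{self.min_mutations}-mutation minimum")
            weights = sigmod.fit_all_weights(
                retained, self.catalog, trim=self.trim, tol=self.fit_tol)
            res.spectra = retained
            res.low_mutation_excluded = excluded
            res.sbs_weights = weights
            res.sbs_dominant = sigmod.dominant_from_weights(weights)
            counts["samples_sbs"] = len(res.sbs_dominant)
            counts["samples_below_min_mutations"] = len(excluded)
            res.sbs_contingency = statsmod.contingency_results(
                label_map, res.sbs_dominant, kind="SBS")
            res.sbs_bootstrap = statsmod.bootstrap_signature_comparison(
                label_map, res.sbs_dominant, R=self.R, seed=seed)

        if self.cn_exposures is not None:
            cn_dom_all = sigmod.dominant_from_exposures(self.cn_exposures)
            res.cn_dominant = {s: g for s, g in cn_dom_all.items() if s in label_map}
            counts["samples_cn"] = len(res.cn_dominant)
            res.cn_contingency = statsmod.contingency_results(
                label_map, res.cn_dominant, kind="CN")
            res.cn_bootstrap = statsmod.bootstrap_signature_comparison(
                label_map, res.cn_dominant, R=self.R, seed=seed)

        if self.features is not None:
            feats = self.features.data.loc[
                [s for s in self.features.data.index if s in label_map]]
            res.feature_forest = statsmod.feature_enrichment(
                feats, label_map, alpha=self.alpha)

        res.correlation, res.correlation_scatter = statsmod.substitution_vaf_correlation(
            self.mutations, self.hallmark_map)
        return res
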