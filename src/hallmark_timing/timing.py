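"""Hallmark VAF profiling and EGI/LGI clustering.

Per patient, the mean VAF of mutations in genes of each of the ten cancer
hallmarks is used as a timing proxy (higher VAF ~ more clonal ~ earlier).
Patients are clustered on these 10-dimensional profiles via PCA (mean
centring, all components retained) followed by k-means with the cluster
count chosen at the elbow of the within-cluster sum-of-squares curve.  The
cluster whose genome-instability hallmark ranks earlier on average is
labelled EGI (early genome instability); the other LGI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .io import (
    CANONICAL_HALLMARKS,
    AssociationResult,
    HallmarkMap,
    MutationRecord,
)
from .stats import bh_adjust

logger = logging.getLogger(__name__)

GENOME_INSTABILITY = "genome_instability"


@dataclass
class HallmarkProfile:
    """Per-patient mean VAF, mutation count and rank for each hallmark."""

    sample_id: str
    mean_vaf: dict[str, float]  # only hallmarks with >= 1 mutation
    n_mut: dict[str, int]
    ranks: dict[str, float] = field(default_factory=dict)  # 1 = highest VAF


@dataclass(frozen=True)
class ClusterLabel:
    sample_id: str
    cluster_index: int
    label: str  # "EGI" | "LGI"
    silhouette: float


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame      # samples x components
    loadings: pd.DataFrame    # hallmarks x components
    var_explained: np.ndarray
    mean: pd.Series


def compute_hallmark_profiles(
    mutations: list[MutationRecord],
    hallmark_map: HallmarkMap,
    impute: bool = False,
) -> list[HallmarkProfile]:
    """Aggregate per-patient mean VAF per hallmark.

    A mutation in a gene mapped to several hallmarks contributes to each of
    them.  With ``impute`` set, hallmarks without mutations are filled with
    the patient's overall mean VAF; otherwise they stay missing (and the
    clustering step will drop incomplete patients).  Patients with zero
    mapped mutations are excluded with a log entry.
    """
    sums: dict[str, dict[str, float]] = {}
    counts: dict[str, dict[str, int]] = {}
    overall_sum: dict[str, float] = {}
    overall_n: dict[str, int] = {}
    n_unmapped = 0
    for m in mutations:
        hs = hallmark_map.hallmarks_of(m.gene)
        if not hs:
            n_unmapped += 1
            continue
        s = sums.setdefault(m.sample_id, {})
        c = counts.setdefault(m.sample_id, {})
        overall_sum[m.sample_id] = overall_sum.get(m.sample_id, 0.0) + m.vaf
        overall_n[m.sample_id] = overall_n.get(m.sample_id, 0) + 1
        for h in hs:
            s[h] = s.get(h, 0.0) + m.vaf
            c[h] = c.get(h, 0) + 1
    if n_unmapped:
        logger.info("compute_hallmark_profiles: %d mutation(s) in unmapped genes", n_unmapped)

    all_samples = {m.sample_id for m in mutations}
    excluded = sorted(all_samples - set(sums))
    if excluded:
        logger.info("excluded %d patient(s) with zero mapped mutations", len(excluded))

    profiles = []
    for sid in sums:
        mean_vaf = {h: sums[sid][h] / counts[sid][h] for h in sums[sid]}
        n_mut = dict(counts[sid])
        if impute:
            overall = overall_sum[sid] / overall_n[sid]
            for h in hallmark_map.hallmarks:
                if h not in mean_vaf:
                    mean_vaf[h] = overall
                    n_mut[h] = 0
        profiles.append(HallmarkProfile(sample_id=sid, mean_vaf=mean_vaf, n_mut=n_mut))
    return profiles


def rank_hallmarks(profile: HallmarkProfile) -> HallmarkProfile:
    """Assign descending-VAF ranks (1 = highest = inferred earliest).

    Ties receive the average of the tied rank positions.  Modifies and
    returns the profile.
    """
    items = list(profile.mean_vaf.items())
    if len(items) < 2:
        raise ValueError(f"{profile.sample_id}: need >= 2 non-missing hallmarks to rank")
    vals = np.array([v for _, v in items])
    # rankdata ranks ascending; rank descending by negating
    ranks = stats.rankdata(-vals, method="average")
    profile.ranks = {h: float(r) for (h, _), r in zip(items, ranks)}
    return profile


def profile_matrix(
    profiles: list[HallmarkProfile],
    hallmarks: tuple[str, ...] = CANONICAL_HALLMARKS,
    require_complete: bool = True,
) -> pd.DataFrame:
    """Stack profiles into a samples x hallmarks mean-VAF matrix.

    With ``require_complete`` patients missing any hallmark are dropped
    (logged); otherwise missing cells become NaN.
    """
    rows = {p.sample_id: [p.mean_vaf.get(h, np.nan) for h in hallmarks] for p in profiles}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(hallmarks))
    if require_complete:
        incomplete = df.index[df.isna().any(axis=1)]
        if len(incomplete):
            logger.info("dropping %d patient(s) with missing hallmarks", len(incomplete))
            df = df.drop(index=incomplete)
    return df


def run_pca(matrix: pd.DataFrame) -> PcaResult:
    """Mean-centred (not variance-scaled) PCA retaining all components."""
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; use impute or drop first")
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 hallmarks")
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    xc = x - mean
    # full SVD keeps every component so k-means on scores == k-means on xc
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    scores = u * s
    var = s**2
    var_explained = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    comps = [f"PC{i + 1}" for i in range(len(s))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comps),
        loadings=pd.DataFrame(vt.T, index=matrix.columns, columns=comps),
        var_explained=var_explained,
        mean=pd.Series(mean, index=matrix.columns),
    )


def _kmeans(x: np.ndarray, k: int, seed: int, n_init: int) -> KMeans:
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_init, max_iter=300,
        tol=1e-6, random_state=seed,
    )
    km.fit(x)
    return km


def wss_curve(
    scores: pd.DataFrame, k_min: int = 1, k_max: int = 10,
    seed: int = 123, n_init: int = 25,
) -> list[tuple[int, float]]:
    """Best within-cluster sum of squares over restarts, for each k."""
    x = scores.to_numpy(dtype=float)
    if k_max >= x.shape[0]:
        raise ValueError(f"k_max={k_max} must be < n_samples={x.shape[0]}")
    curve = []
    for k in range(k_min, k_max + 1):
        if k == 1:
            wss = float(((x - x.mean(axis=0)) ** 2).sum())
        else:
            wss = float(_kmeans(x, k, seed, n_init).inertia_)
        curve.append((k, wss))
    for (k0, w0), (k1, w1) in zip(curve, curve[1:]):
        if w1 > w0 + 1e-9:
            logger.warning("WSS increased from k=%d to k=%d (%.4g -> %.4g)", k0, k1, w0, w1)
    return curve


def select_k_elbow(curve: list[tuple[int, float]]) -> int:
    """Elbow rule: the k maximizing the second forward difference
    WSS(k-1) - 2*WSS(k) + WSS(k+1); ties broken toward the smallest k."""
    if len(curve) < 3:
        raise ValueError("elbow selection needs >= 3 (k, WSS) points")
    ks = [k for k, _ in curve]
    ws = [w for _, w in curve]
    best_k, best_d2 = None, -np.inf
    for i in range(1, len(curve) - 1):
        d2 = ws[i - 1] - 2 * ws[i] + ws[i + 1]
        if d2 > best_d2 + 1e-12:
            best_k, best_d2 = ks[i], d2
    if best_d2 <= 1e-12:
        logger.warning("no clear elbow (near-linear WSS decay); returning smallest interior k")
        return ks[1]
    return best_k


def kmeans_assign(
    scores: pd.DataFrame, k: int, seed: int = 123, n_init: int = 25
) -> pd.Series:
    """k-means cluster assignment (k-means++ init, best of ``n_init``)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    x = scores.to_numpy(dtype=float)
    km = _kmeans(x, k, seed, n_init)
    return pd.Series(km.labels_, index=scores.index, name="cluster")


def silhouette_widths(
    scores: pd.DataFrame, assignments: pd.Series
) -> tuple[pd.Series, float]:
    """Euclidean silhouette width per sample and the average width.

    Samples in singleton clusters get width 0 (scikit-learn's convention).
    """
    labels = assignments.loc[scores.index].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires k >= 2")
    widths = silhouette_samples(scores.to_numpy(dtype=float), labels, metric="euclidean")
    s = pd.Series(widths, index=scores.index, name="silhouette")
    return s, float(widths.mean())


def label_egi_lgi(
    assignments: pd.Series,
    profiles: list[HallmarkProfile],
    silhouettes: pd.Series | None = None,
) -> tuple[list[ClusterLabel], float]:
    """Name the two clusters by genome-instability timing.

    The cluster with the *lower* mean rank of the genome-instability
    hallmark (i.e. acquired earlier) becomes EGI; the other LGI.  Returns
    the labels and the margin between the two cluster mean ranks as a
    confidence diagnostic.
    """
    uniq = sorted(assignments.unique())
    if len(uniq) != 2:
        raise ValueError(f"EGI/LGI labelling requires exactly 2 clusters, got {len(uniq)}")
    by_sample = {p.sample_id: p for p in profiles}
    mean_rank = {}
    for c in uniq:
        sids = assignments.index[assignments == c]
        ranks = [by_sample[s].ranks[GENOME_INSTABILITY]
                 for s in sids
                 if s in by_sample and GENOME_INSTABILITY in by_sample[s].ranks]
        if not ranks:
            raise ValueError(f"cluster {c} has no genome-instability rank data")
        mean_rank[c] = float(np.mean(ranks))
    margin = abs(mean_rank[uniq[0]] - mean_rank[uniq[1]])
    if margin < 1e-9:
        raise ValueError("indistinguishable clusters: equal mean genome-instability ranks")
    egi_cluster = min(uniq, key=lambda c: mean_rank[c])
    labels = []
    for sid, c in assignments.items():
        labels.append(ClusterLabel(
            sample_id=sid,
            cluster_index=int(c),
            label="EGI" if c == egi_cluster else "LGI",
            silhouette=float(silhouettes.loc[sid]) if silhouettes is not None else np.nan,
        ))
    return labels, margin


def compare_hallmark_vaf(
    profiles: list[HallmarkProfile],
    labels: list[ClusterLabel],
    hallmarks: tuple[str, ...] = CANONICAL_HALLMARKS,
) -> list[AssociationResult]:
    """Per-hallmark Mann–Whitney U comparison of mean-VAF distributions
    between the EGI and LGI clusters, BH-adjusted across hallmarks.

    The estimate reported is the median VAF difference (LGI - EGI).  The
    exact null distribution is enumerated when both groups have n <= 8 (and
    no ties); otherwise the normal approximation with tie correction is
    used.
    """
    lab = {l.sample_id: l.label for l in labels}
    results: list[AssociationResult] = []
    pvals: list[float] = []
    kept: list[tuple[str, float, float]] = []
    for h in hallmarks:
        egi = [p.mean_vaf[h] for p in profiles if h in p.mean_vaf and lab.get(p.sample_id) == "EGI"]
        lgi = [p.mean_vaf[h] for p in profiles if h in p.mean_vaf and lab.get(p.sample_id) == "LGI"]
        if len(egi) < 2 or len(lgi) < 2:
            logger.info("hallmark %s skipped: <2 observations in a cluster", h)
            continue
        method = "exact" if (max(len(egi), len(lgi)) <= 8
                             and len(set(egi + lgi)) == len(egi) + len(lgi)) else "asymptotic"
        res = stats.mannwhitneyu(lgi, egi, alternative="two-sided", method=method)
        diff = float(np.median(lgi) - np.median(egi))
        kept.append((h, diff, float(res.pvalue)))
        pvals.append(float(res.pvalue))
    padj = bh_adjust(pvals)
    for (h, diff, p), pa in zip(kept, padj):
        direction = "none"
        if pa < 0.05:
            direction = "LGI" if diff > 0 else "EGI"
        results.append(AssociationResult(
            feature=h, estimate=diff, ci_lo=np.nan, ci_hi=np.nan,
            p_raw=p, p_adj=pa, method="mannwhitney_bh", direction=direction,
        ))
    return results
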