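"""Cluster-association statistics.

Everything that relates the EGI/LGI labels to other per-patient data lives
here: per-signature 2x2 contingency tests (chi-square when all expected
cells are >= 5, Fisher's exact otherwise) with Benjamini–Hochberg FDR
control; the bootstrap comparison of dominant-signature counts between
clusters (Anderson–Darling two-sample test on the replicate distributions,
Cohen's d with a 95% CI); univariate logistic odds ratios per immune/
stemness feature with Bonferroni control; and the substitution-type vs VAF
Pearson-correlation control.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .channels import classify_sbs96
from .io import AssociationResult, HallmarkMap, MutationRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# contingency analysis of dominant signatures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for (dominant-for-signature yes/no) x (EGI / LGI)."""

    a: int  # dominant & EGI
    b: int  # dominant & LGI
    c: int  # not dominant & EGI
    d: int  # not dominant & LGI

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def dominant_count_tables(
    labels: dict[str, str], dominant_calls: dict[str, str]
) -> dict[str, ContingencyTable2x2]:
    """One 2x2 table per signature: dominant-vs-not by EGI/LGI.

    ``dominant_calls`` maps sample_id -> its dominant signature name.
    """
    unlabeled = [s for s in dominant_calls if s not in labels]
    if unlabeled:
        raise ValueError(f"sample(s) without cluster label: {unlabeled[:5]}")
    n_egi = sum(1 for s in dominant_calls if labels[s] == "EGI")
    n_lgi = sum(1 for s in dominant_calls if labels[s] == "LGI")
    signatures = sorted(set(dominant_calls.values()))
    tables = {}
    for sig in signatures:
        a = sum(1 for s, g in dominant_calls.items() if g == sig and labels[s] == "EGI")
        b = sum(1 for s, g in dominant_calls.items() if g == sig and labels[s] == "LGI")
        tables[sig] = ContingencyTable2x2(a=a, b=b, c=n_egi - a, d=n_lgi - b)
    return tables


def contingency_p_value(table: ContingencyTable2x2) -> tuple[float, str]:
    """p-value for a 2x2 table: Pearson chi-square (no continuity
    correction) when all expected frequencies are >= 5, otherwise the
    two-sided Fisher exact test (sum of hypergeometric probabilities <= the
    observed table's).  Zero-margin tables return p = 1, tagged degenerate.
    """
    arr = table.as_array()
    if table.total == 0:
        raise ValueError("empty contingency table")
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return 1.0, "degenerate"
    expected = np.outer(rows, cols) / table.total
    if (expected >= 5).all():
        stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
        return float(p), "chi2"
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return float(p), "fisher"


def bh_adjust(p_values: list[float] | np.ndarray) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def bonferroni_adjust(p_values: list[float] | np.ndarray) -> list[float]:
    """Bonferroni adjusted p-values: p * m capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(np.minimum(p * p.size, 1.0))


def contingency_results(
    labels: dict[str, str], dominant_calls: dict[str, str], kind: str
) -> list[AssociationResult]:
    """Per-signature contingency tests with BH adjustment (one family)."""
    tables = dominant_count_tables(labels, dominant_calls)
    sigs, pvals, methods, tabs = [], [], [], []
    for sig, tab in tables.items():
        if tab.a + tab.b == 0:
            logger.info("signature %s never dominant; test skipped", sig)
            continue
        p, method = contingency_p_value(tab)
        sigs.append(sig)
        pvals.append(p)
        methods.append(method)
        tabs.append(tab)
    padj = bh_adjust(pvals)
    out = []
    for sig, p, pa, method, tab in zip(sigs, pvals, padj, methods, tabs):
        # enrichment direction from the dominant-fraction difference
        f_egi = tab.a / (tab.a + tab.c) if tab.a + tab.c else 0.0
        f_lgi = tab.b / (tab.b + tab.d) if tab.b + tab.d else 0.0
        direction = "none"
        if pa < 0.05:
            direction = "EGI" if f_egi > f_lgi else "LGI"
        out.append(AssociationResult(
            feature=sig, estimate=f_egi - f_lgi, ci_lo=np.nan, ci_hi=np.nan,
            p_raw=p, p_adj=pa, method=f"{kind}_{method}_bh", direction=direction,
        ))
    return out


# ---------------------------------------------------------------------------
# bootstrap + Anderson–Darling + Cohen's d
# ---------------------------------------------------------------------------


@dataclass
class BootstrapComparison:
    signature: str
    replicate_counts_egi: np.ndarray
    replicate_counts_lgi: np.ndarray
    observed_egi: int
    observed_lgi: int
    ad_statistic: float = np.nan
    ad_p: float = np.nan
    ad_p_adj: float = np.nan
    cohen_d: float = np.nan
    d_ci: tuple[float, float] = (np.nan, np.nan)
    d_bin: str = ""
    degenerate: bool = False


def bootstrap_dominant_counts(
    labels: dict[str, str],
    dominant_calls: dict[str, str],
    R: int = 1000,
    seed: int = 123,
) -> dict[str, BootstrapComparison]:
    """Bootstrap the per-signature dominant-sample counts within clusters.

    Each of the R replicates resamples patients with replacement *within*
    each cluster (cluster sizes preserved) and records, per signature, how
    many resampled patients have it dominant.  Deterministic given seed.
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    rng = np.random.default_rng(seed)
    sigs = sorted(set(dominant_calls.values()))
    sig_idx = {s: i for i, s in enumerate(sigs)}
    groups = {}
    for grp in ("EGI", "LGI"):
        sids = [s for s in dominant_calls if labels.get(s) == grp]
        if not sids:
            raise ValueError(f"cluster {grp} is empty")
        groups[grp] = np.array([sig_idx[dominant_calls[s]] for s in sids])
    reps = {}
    for grp, calls in groups.items():
        n = len(calls)
        counts = np.empty((R, len(sigs)), dtype=int)
        for r in range(R):
            resampled = calls[rng.integers(0, n, size=n)]
            counts[r] = np.bincount(resampled, minlength=len(sigs))
        reps[grp] = counts
    out = {}
    for sig, i in sig_idx.items():
        out[sig] = BootstrapComparison(
            signature=sig,
            replicate_counts_egi=reps["EGI"][:, i],
            replicate_counts_lgi=reps["LGI"][:, i],
            observed_egi=int(np.sum(groups["EGI"] == i)),
            observed_lgi=int(np.sum(groups["LGI"] == i)),
        )
    return out


# -- two-sample Anderson–Darling (Scholz–Stephens k=2, midrank ties) --------

_AD_B0 = np.array([0.675, 1.281, 1.645, 1.960, 2.326, 2.573, 3.085])
_AD_B1 = np.array([-0.245, 0.250, 0.678, 1.149, 1.822, 2.364, 3.615])
_AD_B2 = np.array([-0.105, -0.305, -0.362, -0.391, -0.396, -0.345, -0.154])
_AD_SIG = np.array([0.25, 0.10, 0.05, 0.025, 0.01, 0.005, 0.001])


def _ad2_raw(samples: list[np.ndarray]) -> float:
    """Tie-adjusted k-sample Anderson–Darling criterion A2akN (midranks)."""
    pooled = np.sort(np.concatenate(samples))
    zstar = np.unique(pooled)
    n = np.array([len(s) for s in samples])
    N = int(n.sum())
    lj = np.searchsorted(pooled, zstar, side="right") - np.searchsorted(pooled, zstar, side="left")
    bj = lj.cumsum() - lj / 2.0
    a2 = 0.0
    for s, ni in zip(samples, n):
        s = np.sort(s)
        fij = np.searchsorted(s, zstar, side="right") - np.searchsorted(s, zstar, side="left")
        mij = fij.cumsum() - fij / 2.0
        denom = bj * (N - bj) - N * lj / 4.0
        with np.errstate(divide="ignore", invalid="ignore"):
            inner = lj / N * (N * mij - bj * ni) ** 2 / denom
        a2 += float(np.nansum(inner)) / ni
    return a2 * (N - 1) / N


def _ad2_normalized(samples: list[np.ndarray]) -> float:
    """Standardized k-sample AD statistic (A2akN - (k-1)) / sigma_N."""
    k = len(samples)
    n = np.array([len(s) for s in samples])
    N = int(n.sum())
    H = float((1.0 / n).sum())
    hs = 1.0 / np.arange(1, N)
    h = float(hs.sum())
    g = 0.0
    for i in np.arange(1, N - 1):
        g += float((1.0 / ((N - i) * np.arange(i + 1, N))).sum())
    a = (4 * g - 6) * (k - 1) + (10 - 6 * g) * H
    b = (2 * g - 4) * k**2 + 8 * h * k + (2 * g - 14 * h - 4) * H - 8 * h + 4 * g - 6
    c = (6 * h + 2 * g - 2) * k**2 + (4 * h - 4 * g + 6) * k + (2 * h - 6) * H + 4 * h
    d = (2 * h + 6) * k**2 - 4 * h * k
    sigmasq = (a * N**3 + b * N**2 + c * N + d) / ((N - 1.0) * (N - 2.0) * (N - 3.0))
    return (_ad2_raw(samples) - (k - 1)) / np.sqrt(sigmasq)


def _ad_asymptotic_p(tk: float, k: int) -> float:
    """Asymptotic right-tail p for the standardized statistic, via the
    Scholz–Stephens critical-value interpolation (extrapolated beyond the
    tabulated [0.001, 0.25] range rather than clipped, so that downstream
    FDR adjustment sees informative p-values)."""
    m = k - 1
    critical = _AD_B0 + _AD_B1 / np.sqrt(m) + _AD_B2 / m
    pf = np.polyfit(critical, np.log(_AD_SIG), 2)
    # the fitted parabola is only monotone decreasing up to (or from) its
    # vertex; clamp tk to the monotone branch so extreme statistics map to
    # extreme p-values instead of folding back
    vertex = -pf[1] / (2 * pf[0])
    tk_eff = min(tk, vertex) if pf[0] > 0 else max(tk, vertex)
    logp = np.polyval(pf, tk_eff)
    return float(np.exp(min(logp, 0.0)))


def ad_ksample_test(
    x: np.ndarray | list[float], y: np.ndarray | list[float]
) -> tuple[float, float, bool]:
    """Two-sample Anderson–Darling test (midrank tie handling).

    Returns ``(standardized statistic, p, degenerate_flag)``.  For a pooled
    sample of at most 12 observations the p-value is computed by exhaustive
    permutation enumeration; otherwise the asymptotic interpolation is used.
    A constant pooled sample yields p = 1 with the degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 observations")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0, True
    tk = _ad2_normalized([x, y])
    N = len(pooled)
    if N <= 12:
        nx = len(x)
        count = 0
        total = 0
        idx_all = frozenset(range(N))
        for combo in itertools.combinations(range(N), nx):
            xi = pooled[list(combo)]
            yi = pooled[sorted(idx_all - set(combo))]
            if _ad2_normalized([xi, yi]) >= tk - 1e-12:
                count += 1
            total += 1
        return tk, count / total, False
    return tk, _ad_asymptotic_p(tk, k=2), False


def cohens_d_ci(
    x: np.ndarray | list[float], y: np.ndarray | list[float], confidence: float = 0.95
) -> tuple[float, tuple[float, float], str]:
    """Cohen's d (pooled SD, n-1 denominators), normal-approximation CI and
    the negligible/small/medium/large bin (cuts at |d| = 0.2, 0.5, 0.8)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs >= 2 observations")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 <= 0:
        raise ValueError("pooled SD is zero; Cohen's d undefined")
    d = (x.mean() - y.mean()) / np.sqrt(sp2)
    se = np.sqrt((nx + ny) / (nx * ny) + d**2 / (2 * (nx + ny - 2)))
    z = sps.norm.ppf(0.5 + confidence / 2)
    lo, hi = d - z * se, d + z * se
    ad = abs(d)
    if ad < 0.2:
        bin_ = "negligible"
    elif ad < 0.5:
        bin_ = "small"
    elif ad < 0.8:
        bin_ = "medium"
    else:
        bin_ = "large"
    return float(d), (float(lo), float(hi)), bin_


def bootstrap_signature_comparison(
    labels: dict[str, str],
    dominant_calls: dict[str, str],
    R: int = 1000,
    seed: int = 123,
) -> list[BootstrapComparison]:
    """Full bootstrap pipeline per signature: replicate counts, AD test on
    the replicate distributions, BH across signatures, Cohen's d + CI."""
    comps = bootstrap_dominant_counts(labels, dominant_calls, R=R, seed=seed)
    ordered = [comps[s] for s in sorted(comps)]
    pvals = []
    for comp in ordered:
        stat, p, degen = ad_ksample_test(
            comp.replicate_counts_egi, comp.replicate_counts_lgi)
        comp.ad_statistic = stat
        comp.ad_p = p
        comp.degenerate = degen
        try:
            comp.cohen_d, comp.d_ci, comp.d_bin = cohens_d_ci(
                comp.replicate_counts_egi, comp.replicate_counts_lgi)
        except ValueError:
            comp.degenerate = True
        pvals.append(p)
    for comp, pa in zip(ordered, bh_adjust(pvals)):
        comp.ad_p_adj = pa
    return ordered


# ---------------------------------------------------------------------------
# logistic odds ratios
# ---------------------------------------------------------------------------


def logistic_or(
    feature_values: pd.Series,
    labels: dict[str, str],
    feature_name: str | None = None,
) -> AssociationResult:
    """Univariate logistic regression of cluster on one feature.

    LGI is coded 1, so OR > 1 means LGI-association and OR < 1 means
    EGI-association.  Missing feature values are dropped pairwise.
    Quasi-complete separation (diverging slope) is flagged and the OR
    reported as a bound; a constant feature yields OR = 1, degenerate.
    """
    name = feature_name or str(feature_values.name)
    lab = pd.Series({s: labels[s] for s in feature_values.index if s in labels})
    x = feature_values.loc[lab.index].astype(float)
    keep = x.notna()
    x, lab = x[keep], lab[keep]
    y = (lab == "LGI").astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError("both clusters must be present")
    if (y == 1).sum() < 1 or (y == 0).sum() < 1:
        raise ValueError("need >= 1 non-missing value per class")
    xv = x.to_numpy()
    if np.ptp(xv) == 0:
        return AssociationResult(
            feature=name, estimate=1.0, ci_lo=1.0, ci_hi=1.0, p_raw=1.0,
            p_adj=np.nan, method="logistic_or", direction="none",
            note="degenerate: constant feature",
        )
    exog = sm.add_constant(xv)
    note = ""
    try:
        fit = sm.Logit(y, exog).fit(disp=0, method="newton", maxiter=100, tol=1e-8)
        slope = fit.params[1]
        se = fit.bse[1]
        p = float(fit.pvalues[1])
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:  # perfect separation raises in statsmodels
        converged = False
        slope, se, p = np.nan, np.nan, np.nan
    if not converged or not np.isfinite(slope) or abs(slope) > 30 / max(np.std(xv), 1e-12):
        # quasi-complete separation: report direction as a bound
        direction = "LGI" if np.nanmean(xv[y == 1]) > np.nanmean(xv[y == 0]) else "EGI"
        bound = np.inf if direction == "LGI" else 0.0
        return AssociationResult(
            feature=name, estimate=bound, ci_lo=0.0, ci_hi=np.inf, p_raw=np.nan,
            p_adj=np.nan, method="logistic_or", direction=direction,
            note="separation: OR reported as bound",
        )
    z = sps.norm.ppf(0.975)
    orr = float(np.exp(slope))
    return AssociationResult(
        feature=name, estimate=orr,
        ci_lo=float(np.exp(slope - z * se)), ci_hi=float(np.exp(slope + z * se)),
        p_raw=p, p_adj=np.nan, method="logistic_or",
        direction="none", note=note,
    )


def feature_enrichment(
    features: pd.DataFrame, labels: dict[str, str], alpha: float = 0.05
) -> list[AssociationResult]:
    """Per-feature logistic ORs with Bonferroni adjustment (forest table)."""
    rows = []
    for col in features.columns:
        rows.append(logistic_or(features[col], labels, feature_name=col))
    testable = [r for r in rows if np.isfinite(r.p_raw)]
    padj = bonferroni_adjust([r.p_raw for r in testable])
    adj_map = {id(r): pa for r, pa in zip(testable, padj)}
    out = []
    for r in rows:
        pa = adj_map.get(id(r), np.nan)
        direction = r.direction
        if np.isfinite(pa):
            direction = ("LGI" if r.estimate > 1 else "EGI") if pa < alpha else "none"
        out.append(AssociationResult(
            feature=r.feature, estimate=r.estimate, ci_lo=r.ci_lo, ci_hi=r.ci_hi,
            p_raw=r.p_raw, p_adj=pa, method="logistic_or_bonferroni",
            direction=direction, note=r.note,
        ))
    return out


# ---------------------------------------------------------------------------
# substitution-type vs VAF correlation control
# ---------------------------------------------------------------------------


def substitution_vaf_correlation(
    mutations: list[MutationRecord],
    hallmark_map: HallmarkMap,
    min_genes: int = 3,
) -> tuple[list[AssociationResult], pd.DataFrame]:
    """Pearson correlation between per-gene substitution counts and mean VAF.

    Only single-nucleotide substitutions in hallmark-mapped genes are used.
    Substitutions are grouped by (gene, pyrimidine-normalized class); per
    class the correlation across genes between occurrence count and mean VAF
    is tested.  Classes observed in fewer than ``min_genes`` genes are
    skipped.  Returns the per-class results and the per-(gene, class)
    scatter table.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    for m in mutations:
        if not hallmark_map.hallmarks_of(m.gene):
            continue
        if len(m.ref) != 1 or len(m.alt) != 1:
            continue
        if m.ref not in "ACGT" or m.alt not in "ACGT" or m.ref == m.alt:
            continue
        ctx = m.context3 if m.context3 is not None else "A" + m.ref + "A"
        ch = classify_sbs96(m.ref, m.alt, ctx)
        if not isinstance(ch, str):
            continue
        subtype = ch[2:5]  # e.g. "C>A"
        groups.setdefault((m.gene, subtype), []).append(m.vaf)

    scatter = pd.DataFrame(
        [(g, t, len(v), float(np.mean(v))) for (g, t), v in sorted(groups.items())],
        columns=["gene", "substitution", "count", "mean_vaf"],
    )
    results = []
    for subtype in sorted(scatter["substitution"].unique()):
        sub = scatter[scatter["substitution"] == subtype]
        if len(sub) < min_genes:
            logger.info("substitution %s observed in <%d genes; skipped", subtype, min_genes)
            continue
        if sub["count"].nunique() == 1 or sub["mean_vaf"].nunique() == 1:
            results.append(AssociationResult(
                feature=subtype, estimate=np.nan, ci_lo=np.nan, ci_hi=np.nan,
                p_raw=np.nan, p_adj=np.nan, method="pearson",
                note="degenerate: constant input",
            ))
            continue
        res = sps.pearsonr(sub["count"], sub["mean_vaf"])
        ci = res.confidence_interval(0.95)
        results.append(AssociationResult(
            feature=subtype, estimate=float(res.statistic),
            ci_lo=float(ci.low), ci_hi=float(ci.high),
            p_raw=float(res.pvalue), p_adj=np.nan, method="pearson",
        ))
    return results, scatter
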