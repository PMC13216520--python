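"""SBS96 spectra, signature refitting and dominant-signature calls.

The refit follows the deconstructSigs scheme: starting from an all-zero
weight vector, signatures are greedily added/adjusted — at each step the
candidate whose golden-section-optimized weight most reduces the
sum-of-squared error between the weighted catalog mix and the observed
96-channel fraction vector is updated — until the SSE improvement drops
below tolerance.  Normalized weights below the trim threshold (default
0.06) are zeroed and the surviving signatures refit.  Samples with fewer
than 50 classified mutations are excluded before fitting, the minimum for
a reliable decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import (
    CN_CHANNEL_COUNT,
    SBS96_CHANNELS,
    CHANNEL_INDEX,
    Rejection,
    classify_sbs96,
)
from .io import ExposureMatrix, MutationRecord, SignatureCatalog

logger = logging.getLogger(__name__)

MIN_MUTATIONS = 50  # minimum classified SNVs for signature decomposition


@dataclass
class Sbs96Spectrum:
    """Per-sample counts over the 96 canonical channels."""

    sample_id: str
    counts: np.ndarray  # length 96, canonical channel order

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def fractions(self) -> np.ndarray:
        t = self.total
        if t == 0:
            raise ValueError(f"{self.sample_id}: zero-total spectrum")
        return self.counts / t


@dataclass(frozen=True)
class SignatureWeights:
    sample_id: str
    weights: dict[str, float]  # retained signatures only, each >= trim
    unexplained: float
    n_mutations: int
    sse: float


@dataclass(frozen=True)
class DominantCall:
    sample_id: str
    signature: str
    weight_or_exposure: float
    kind: str  # "SBS" | "CN"
    tie_flag: bool = False


def resolve_contexts(
    mutations: list[MutationRecord], fasta_path: str
) -> list[MutationRecord]:
    """Fill missing trinucleotide contexts from a reference FASTA."""
    from pyfaidx import Fasta  # optional dependency path
    from dataclasses import replace

    fa = Fasta(fasta_path)
    out = []
    for m in mutations:
        if m.context3 is not None or len(m.ref) != 1:
            out.append(m)
            continue
        seq = str(fa[m.chrom][m.pos - 2 : m.pos + 1]).upper()
        out.append(replace(m, context3=seq if len(seq) == 3 else None))
    return out


def build_spectra(
    mutations: list[MutationRecord],
) -> tuple[list[Sbs96Spectrum], dict[str, int]]:
    """Tally per-sample 96-channel spectra; rejections counted by reason."""
    counts: dict[str, np.ndarray] = {}
    rejections: dict[str, int] = {}
    for m in mutations:
        if m.sample_id not in counts:
            counts[m.sample_id] = np.zeros(96, dtype=int)
        if m.context3 is None:
            rejections["missing_context"] = rejections.get("missing_context", 0) + 1
            continue
        ch = classify_sbs96(m.ref, m.alt, m.context3)
        if isinstance(ch, Rejection):
            rejections[ch.reason] = rejections.get(ch.reason, 0) + 1
            continue
        counts[m.sample_id][CHANNEL_INDEX[ch]] += 1
    spectra = [Sbs96Spectrum(sid, c) for sid, c in counts.items()]
    if rejections:
        logger.info("build_spectra rejections: %s", rejections)
    return spectra, rejections


def apply_min_mutation_filter(
    spectra: list[Sbs96Spectrum], threshold: int = MIN_MUTATIONS
) -> tuple[list[Sbs96Spectrum], list[str]]:
    """Drop samples with fewer than ``threshold`` classified mutations."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    retained = [s for s in spectra if s.total >= threshold]
    excluded = [s.sample_id for s in spectra if s.total < threshold]
    if excluded:
        logger.info("min-mutation filter (<%d): excluded %d sample(s)",
                    threshold, len(excluded))
    if not retained:
        logger.warning("min-mutation filter removed every sample")
    return retained, excluded


def _golden_min(f, lo: float, hi: float, tol: float = 1e-7) -> float:
    """Golden-section search for the minimizer of a unimodal f on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def _greedy_fit(
    target: np.ndarray, catalog: np.ndarray, tol: float, max_iter: int = 100
) -> np.ndarray:
    """Greedy forward-selection fit of nonnegative weights (see module doc)."""
    n_sig = catalog.shape[1]
    w = np.zeros(n_sig)

    def sse_of(weights: np.ndarray) -> float:
        resid = target - catalog @ weights
        return float(resid @ resid)

    current = sse_of(w)
    for _ in range(max_iter):
        best_i, best_x, best_sse = -1, 0.0, current
        for i in range(n_sig):
            others = catalog @ w - catalog[:, i] * w[i]
            resid = target - others
            col = catalog[:, i]

            def f(x, resid=resid, col=col):
                r = resid - x * col
                return float(r @ r)

            x_star = _golden_min(f, 0.0, 1.0)
            s = f(x_star)
            if s < best_sse - 1e-15:
                best_i, best_x, best_sse = i, x_star, s
        if best_i < 0 or current - best_sse < tol:
            break
        w[best_i] = best_x
        current = best_sse
    return w


def fit_signature_weights(
    spectrum: Sbs96Spectrum,
    catalog: SignatureCatalog,
    trim: float = 0.06,
    tol: float = 1e-3,
) -> SignatureWeights:
    """Refit a sample's 96-channel spectrum against a reference catalog.

    Returns retained signature weights (each >= ``trim`` after
    normalization), the unexplained residual mass 1 - sum(weights) bounded
    below at 0, and the final SSE of the reconstruction.
    """
    if list(catalog.channels) != list(SBS96_CHANNELS):
        raise ValueError("catalog channels not in canonical order")
    target = spectrum.fractions()
    cat = catalog.data.to_numpy(dtype=float)
    names = list(catalog.signatures)

    w = _greedy_fit(target, cat, tol)
    # trim on the normalized scale, then refit the survivors; repeat until
    # every retained weight clears the threshold
    active = np.arange(len(names))
    for _ in range(len(names)):
        total = w.sum()
        if total <= 0:
            break
        norm = w / total
        keep = norm >= trim
        if keep.all():
            break
        if not keep.any():
            keep = norm == norm.max()
        active = active[keep]
        w = _greedy_fit(target, cat[:, active], tol)
    total = w.sum()
    if total > 1.0:
        w = w / total
        total = 1.0
    resid = target - cat[:, active] @ w if len(active) else target
    weights = {names[a]: float(x) for a, x in zip(active, w) if x > 0}
    return SignatureWeights(
        sample_id=spectrum.sample_id,
        weights=weights,
        unexplained=float(max(0.0, 1.0 - total)),
        n_mutations=spectrum.total,
        sse=float(resid @ resid),
    )


def fit_all_weights(
    spectra: list[Sbs96Spectrum],
    catalog: SignatureCatalog,
    trim: float = 0.06,
    tol: float = 1e-3,
) -> list[SignatureWeights]:
    return [fit_signature_weights(s, catalog, trim=trim, tol=tol) for s in spectra]


def dominant_signature(
    row: dict[str, float] | pd.Series, sample_id: str, kind: str
) -> DominantCall:
    """Argmax signature of one weight/exposure row; exact ties resolve to
    the lexicographically smallest name with the tie flag set."""
    items = dict(row)
    if not items:
        raise ValueError("empty signature row")
    vmax = max(items.values())
    if vmax <= 0:
        raise ValueError(f"{sample_id}: no attributable signature (all-zero row)")
    winners = sorted(name for name, v in items.items() if v == vmax)
    return DominantCall(
        sample_id=sample_id,
        signature=winners[0],
        weight_or_exposure=float(vmax),
        kind=kind,
        tie_flag=len(winners) > 1,
    )


def dominant_from_weights(weights: list[SignatureWeights]) -> dict[str, str]:
    out = {}
    for w in weights:
        if not w.weights:
            logger.info("%s: no retained signatures; dominant call skipped", w.sample_id)
            continue
        out[w.sample_id] = dominant_signature(w.weights, w.sample_id, "SBS").signature
    return out


def dominant_from_exposures(exposures: ExposureMatrix) -> dict[str, str]:
    out = {}
    for sid, row in exposures.data.iterrows():
        out[str(sid)] = dominant_signature(row.to_dict(), str(sid), exposures.kind).signature
    return out


def check_cn_catalog(catalog: pd.DataFrame) -> None:
    """Validate that a supplied CN catalog uses the 48-channel scheme."""
    if catalog.shape[0] != CN_CHANNEL_COUNT:
        raise ValueError(
            f"CN catalog must have {CN_CHANNEL_COUNT} channel rows, got {catalog.shape[0]}")


def weights_frame(weights: list[SignatureWeights], signatures: list[str]) -> pd.DataFrame:
    """Stack fitted weights into a samples x signatures DataFrame
    (including an ``unexplained`` column)."""
    rows = {
        w.sample_id: [w.weights.get(s, 0.0) for s in signatures] + [w.unexplained]
        for w in weights
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(signatures) + ["unexplained"]
    )
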