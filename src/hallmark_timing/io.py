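"""Readers and writers for the tab-delimited tables the pipeline consumes.

All inputs are UTF-8 TSV with a header row; ``.``, ``NA`` and empty cells
denote missing values.  Coordinates are 1-based (MAF convention) and the
trinucleotide context, when present, is reported on the plus strand.
Downstream modules consume only the domain types defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import CHANNEL_INDEX, SBS96_CHANNELS

logger = logging.getLogger(__name__)

NA_VALUES = (".", "NA", "")

#: The ten canonical cancer hallmarks, in the naming used throughout.
CANONICAL_HALLMARKS = (
    "genome_instability",
    "immune_evasion",
    "inflammation",
    "proliferation",
    "growth_suppressors",
    "apoptosis",
    "immortality",
    "angiogenesis",
    "invasion_metastasis",
    "energetics",
)


class FormatError(ValueError):
    """A file does not conform to the expected table format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class MutationRecord:
    """One somatic variant: sample, gene, position, alleles, VAF, context."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    context3: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"pos {self.pos} must be >= 1 (1-based)")
        if self.context3 is not None:
            if len(self.context3) != 3:
                raise ValueError(f"context3 {self.context3!r} must have length 3")
            if len(self.ref) == 1 and self.context3[1] != self.ref:
                raise ValueError(
                    f"context3 {self.context3!r} middle base != ref {self.ref!r}"
                )
        if len(self.ref) == 1 and len(self.alt) == 1 and self.ref == self.alt:
            raise ValueError("ref equals alt for a substitution")


@dataclass(frozen=True)
class HallmarkMap:
    """Gene -> set of hallmark names; a gene may serve several hallmarks."""

    entries: Mapping[str, frozenset[str]]
    hallmarks: tuple[str, ...] = CANONICAL_HALLMARKS

    def __post_init__(self) -> None:
        valid = set(self.hallmarks)
        for gene, hs in self.entries.items():
            unknown = set(hs) - valid
            if unknown:
                raise ValueError(f"gene {gene}: unknown hallmarks {sorted(unknown)}")

    def hallmarks_of(self, gene: str) -> frozenset[str]:
        return self.entries.get(gene, frozenset())


@dataclass(frozen=True)
class SignatureCatalog:
    """Reference signature spectra: channels x signatures, columns sum to 1."""

    data: pd.DataFrame  # index = channel names, columns = signature names

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("catalog contains negative entries")
        sums = self.data.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = sums[~np.isclose(sums, 1.0, atol=1e-6)].index.tolist()
            raise ValueError(f"signature columns do not sum to 1: {bad}")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def signatures(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def spectrum(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


@dataclass(frozen=True)
class ExposureMatrix:
    """Per-sample signature exposures (SBS weights or CN activities)."""

    data: pd.DataFrame  # index = sample_id, columns = signature names
    kind: str  # "SBS" | "CN"

    def __post_init__(self) -> None:
        if self.kind not in ("SBS", "CN"):
            raise ValueError(f"kind must be 'SBS' or 'CN', got {self.kind!r}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("exposures must be nonnegative")
        if self.data.shape[1] < 1:
            raise ValueError("at least one signature column required")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample_ids in exposure matrix")


@dataclass(frozen=True)
class FeatureTable:
    """Per-sample features (immune fractions, stemness scores, ...).

    Missing values are NaN; ``kinds`` optionally tags each column as
    ``immune_cell`` or ``immune_feature``.
    """

    data: pd.DataFrame  # index = sample_id
    kinds: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_ids: {dups}")


@dataclass(frozen=True)
class AssociationResult:
    """One association-statistic row (estimate, CI, raw/adjusted p)."""

    feature: str
    estimate: float
    ci_lo: float
    ci_hi: float
    p_raw: float
    p_adj: float
    method: str
    direction: str = "none"  # "EGI" | "LGI" | "none"
    note: str = ""


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_MUTATION_COLUMNS = ("sample_id", "gene", "chrom", "pos", "ref", "alt", "vaf")


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise OSError(f"cannot read {path}: no such file")
    return pd.read_csv(
        path, sep="\t", na_values=list(NA_VALUES), keep_default_na=False, **kwargs
    )


def read_mutation_table(
    path: str | Path,
    strict: bool = True,
    column_map: Mapping[str, str] | None = None,
) -> list[MutationRecord]:
    """Read a MAF-like mutation TSV into :class:`MutationRecord` objects.

    ``column_map`` remaps non-standard headers to the required names
    (``sample_id gene chrom pos ref alt vaf`` and optional ``context3``).
    In strict mode a VAF outside [0, 1] raises; otherwise such rows are
    dropped with a logged count.
    """
    df = _read_tsv(path, dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in _MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"mutation table missing required column(s): {missing}")
    has_ctx = "context3" in df.columns
    records: list[MutationRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        vaf = float(getattr(row, "vaf"))
        if not 0.0 <= vaf <= 1.0:
            if strict:
                raise FormatError(f"vaf {vaf} outside [0, 1] for sample {row.sample_id}")
            n_dropped += 1
            continue
        ctx = getattr(row, "context3", None) if has_ctx else None
        if isinstance(ctx, float) and np.isnan(ctx):
            ctx = None
        records.append(
            MutationRecord(
                sample_id=str(row.sample_id),
                gene=str(row.gene),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref).upper(),
                alt=str(row.alt).upper(),
                vaf=vaf,
                context3=None if ctx is None else str(ctx).upper(),
            )
        )
    if n_dropped:
        logger.info("read_mutation_table: dropped %d row(s) with VAF outside [0,1]", n_dropped)
    return records


def read_hallmark_map(
    path: str | Path, hallmarks: Sequence[str] = CANONICAL_HALLMARKS
) -> HallmarkMap:
    """Read a two-column ``gene<TAB>hallmark`` map (one pair per row)."""
    df = _read_tsv(path, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols or "hallmark" not in cols:
        raise FormatError("hallmark map requires 'gene' and 'hallmark' columns")
    entries: dict[str, set[str]] = {}
    for gene, hm in zip(df[cols["gene"]], df[cols["hallmark"]]):
        entries.setdefault(str(gene), set()).add(str(hm))
    return HallmarkMap(
        entries={g: frozenset(h) for g, h in entries.items()},
        hallmarks=tuple(hallmarks),
    )


def read_signature_catalog(path: str | Path) -> SignatureCatalog:
    """Read a COSMIC-style SBS catalog (96 channel rows x signature columns).

    Channels are reordered into the canonical COSMIC ordering; columns within
    1e-3 of unit sum are renormalized, anything further off is an error.
    """
    df = _read_tsv(path, index_col=0)
    if df.shape[0] != 96:
        raise FormatError(f"SBS catalog must have 96 channel rows, got {df.shape[0]}")
    unknown = [ch for ch in df.index if ch not in CHANNEL_INDEX]
    if unknown:
        raise FormatError(f"unrecognized channel name(s): {unknown[:5]}")
    df = df.loc[list(SBS96_CHANNELS)].astype(float)
    if (df.to_numpy() < 0).any():
        raise FormatError("catalog contains negative entries")
    sums = df.sum(axis=0)
    off = sums[np.abs(sums - 1.0) > 1e-3]
    if len(off):
        raise FormatError(
            f"signature column(s) do not sum to 1 within 1e-3: {off.index.tolist()}"
        )
    return SignatureCatalog(df / sums)


def read_exposure_matrix(path: str | Path, kind: str) -> ExposureMatrix:
    """Read a samples x signatures exposure TSV (first column sample_id)."""
    df = _read_tsv(path, index_col=0).astype(float)
    return ExposureMatrix(df, kind=kind)


def read_feature_table(path: str | Path, strict: bool = True) -> FeatureTable:
    """Read a per-sample feature TSV; blanks/NA become missing, never 0."""
    df = _read_tsv(path, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample_id(s): {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if strict:
        bad = numeric.isna() & df.notna()
        if bad.to_numpy().any():
            col = bad.any(axis=0).idxmax()
            raise FormatError(f"non-numeric value in feature column {col!r}")
    return FeatureTable(numeric)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_ASSOC_COLUMNS = (
    "feature", "estimate", "ci_lo", "ci_hi", "p_raw", "p_adj",
    "method", "direction", "note",
)


def association_frame(rows: Iterable[AssociationResult]) -> pd.DataFrame:
    """Collect :class:`AssociationResult` rows into a DataFrame."""
    return pd.DataFrame(
        [[getattr(r, c) for c in _ASSOC_COLUMNS] for r in rows],
        columns=list(_ASSOC_COLUMNS),
    )


def write_association_results(
    rows: Iterable[AssociationResult], path: str | Path
) -> None:
    """Write association rows as TSV with full (repr) float precision."""
    df = association_frame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_association_results(path: str | Path) -> list[AssociationResult]:
    df = _read_tsv(path)
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        d["note"] = "" if pd.isna(d.get("note")) else str(d["note"])
        out.append(AssociationResult(**d))
    return out


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "sample_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.17g")
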