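"""SBS 96-channel classification of single-base substitutions.

Somatic single-base substitutions are conventionally collapsed onto the
pyrimidine strand: a mutation whose reference base is a purine (A or G) is
reverse-complemented, together with its trinucleotide context, before channel
assignment.  Six substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) times 16
flanking-base combinations give the standard 96 channels, written
``5'[REF>ALT]3'`` (e.g. ``A[C>A]A``).
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

BASES = ("A", "C", "G", "T")

#: The six pyrimidine-strand substitution classes, in COSMIC block order.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical 96-channel ordering (COSMIC convention): substitution-class
#: blocks first, flanks alphabetical with the 5' base varying slowest.
SBS96_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX = {ch: i for i, ch in enumerate(SBS96_CHANNELS)}

#: Number of CN classification channels expected of a copy-number catalog.
CN_CHANNEL_COUNT = 48


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string (uppercase)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in {seq!r}") from exc


@dataclass(frozen=True)
class Rejection:
    """Why a variant could not be assigned to one of the 96 channels."""

    reason: str  # "not_snv" | "bad_context" | "context_mismatch"
    detail: str = ""


def classify_sbs96(ref: str, alt: str, context3: str) -> str | Rejection:
    """Assign a substitution to one of the 96 SBS channels.

    Parameters
    ----------
    ref, alt : str
        Reference and alternate alleles.  Anything other than two distinct
        single bases (i.e. insertions, deletions, MNVs) is rejected.
    context3 : str
        Plus-strand trinucleotide centred on the mutated base.

    Returns
    -------
    str or Rejection
        The channel name, e.g. ``"A[C>A]A"``, or a :class:`Rejection`
        explaining why the variant was excluded.
    """
    ref = ref.upper()
    alt = alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
        return Rejection("not_snv", f"{ref}>{alt}")
    if ref == alt:
        return Rejection("not_snv", "ref equals alt")
    context3 = context3.upper()
    if len(context3) != 3 or any(b not in BASES for b in context3):
        return Rejection("bad_context", context3)
    if context3[1] != ref:
        return Rejection("context_mismatch", f"{context3} middle != {ref}")
    if ref in ("A", "G"):  # purine: report on the pyrimidine strand
        context3 = reverse_complement(context3)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    return f"{context3[0]}[{ref}>{alt}]{context3[2]}"


def channel_parts(channel: str) -> tuple[str, str, str, str]:
    """Split ``"A[C>G]T"`` into (5' base, ref, alt, 3' base)."""
    five, rest = channel[0], channel[2:-2]
    ref, alt = rest.split(">")
    return five, ref, alt, channel[-1]
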