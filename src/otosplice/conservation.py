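"""Splice-site context extraction, dinucleotide classing, and conservation.

A splice-site context holds four strand-aware sequence windows around one
junction: the exonic bases upstream of the donor, the intronic flank
starting at the donor dinucleotide, the intronic flank ending at the
acceptor dinucleotide, and the exonic bases downstream of the acceptor —
all written 5'->3' in transcript orientation, exonic windows upper case
and intronic lower case as is conventional in splice-site figures.

Cross-species comparison is ungapped and position-by-position; no
alignment is attempted.  Orthologous windows for the second species must
be supplied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .model import GenomicInterval, Junction, reverse_complement

CANONICAL = "GT_AG"
MINOR_CANONICAL = "GC_AG"
NONCANONICAL = "noncanonical"

WINDOW_NAMES = (
    "exonic_upstream",
    "intronic_donor_flank",
    "intronic_acceptor_flank",
    "exonic_downstream",
)


@dataclass(frozen=True)
class SpliceSiteContext:
    junction: Junction
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    exonic_upstream: str
    intronic_donor_flank: str
    intronic_acceptor_flank: str
    exonic_downstream: str

    def windows(self) -> dict[str, str]:
        return {name: getattr(self, name) for name in WINDOW_NAMES}


@dataclass(frozen=True)
class ConservationReport:
    per_position_matches: dict[str, tuple[bool, ...]]
    percent_identity: float
    donor_class_match: bool
    acceptor_class_match: bool
    species_order: tuple[str, str] = ("species1", "species2")


def extract_context(
    genome_sequence: Mapping[str, str],
    junction: Junction | GenomicInterval,
    exonic_window: int = 9,
    intronic_window: int = 9,
) -> SpliceSiteContext:
    """Extract strand-aware splice-site windows around an intron interval."""
    if exonic_window < 1 or intronic_window < 2:
        raise ValueError("windows must allow at least the donor/acceptor dinucleotide")
    iv = junction.interval if isinstance(junction, Junction) else junction
    chrom_seq = genome_sequence[iv.chrom]
    if iv.length < 2 * intronic_window:
        raise ValueError(
            f"intron of length {iv.length} shorter than twice the intronic window"
        )
    lo = iv.start - exonic_window
    hi = iv.end + exonic_window
    if lo < 1 or hi > len(chrom_seq):
        raise ValueError(
            f"window around {iv.chrom}:{iv.start}-{iv.end} exceeds sequence bounds"
        )

    def fetch(start: int, end: int) -> str:
        seq = chrom_seq[start - 1 : end].upper()
        return reverse_complement(seq) if iv.strand == "-" else seq

    if iv.strand == "+":
        exon_up = fetch(iv.start - exonic_window, iv.start - 1)
        donor_flank = fetch(iv.start, iv.start + intronic_window - 1)
        acceptor_flank = fetch(iv.end - intronic_window + 1, iv.end)
        exon_down = fetch(iv.end + 1, iv.end + exonic_window)
    else:
        exon_up = fetch(iv.end + 1, iv.end + exonic_window)
        donor_flank = fetch(iv.end - intronic_window + 1, iv.end)
        acceptor_flank = fetch(iv.start, iv.start + intronic_window - 1)
        exon_down = fetch(iv.start - exonic_window, iv.start - 1)

    return SpliceSiteContext(
        junction=Junction(
            iv,
            donor_dinucleotide=donor_flank[:2],
            acceptor_dinucleotide=acceptor_flank[-2:],
        ),
        donor_dinucleotide=donor_flank[:2],
        acceptor_dinucleotide=acceptor_flank[-2:],
        exonic_upstream=exon_up.upper(),
        intronic_donor_flank=donor_flank.lower(),
        intronic_acceptor_flank=acceptor_flank.lower(),
        exonic_downstream=exon_down.upper(),
    )


def classify_donor(context: SpliceSiteContext) -> str:
    """Class of the donor/acceptor pair: GT_AG, GC_AG (minor), or noncanonical."""
    donor = context.donor_dinucleotide.upper()
    acceptor = context.acceptor_dinucleotide.upper()
    if acceptor == "AG":
        if donor == "GT":
            return CANONICAL
        if donor == "GC":
            return MINOR_CANONICAL
    return NONCANONICAL


def compare_contexts(
    context_species1: SpliceSiteContext,
    context_species2: SpliceSiteContext,
    species_order: tuple[str, str] = ("species1", "species2"),
) -> ConservationReport:
    """Ungapped positional comparison of two equally-configured contexts."""
    w1, w2 = context_species1.windows(), context_species2.windows()
    matches: dict[str, tuple[bool, ...]] = {}
    n_match = n_total = 0
    for name in WINDOW_NAMES:
        a, b = w1[name].upper(), w2[name].upper()
        if len(a) != len(b):
            raise ValueError(f"window {name!r} lengths differ: {len(a)} vs {len(b)}")
        flags = tuple(x == y for x, y in zip(a, b))
        matches[name] = flags
        n_match += sum(flags)
        n_total += len(flags)
    return ConservationReport(
        per_position_matches=matches,
        percent_identity=100.0 * n_match / n_total if n_total else 0.0,
        donor_class_match=classify_donor(context_species1)
        == classify_donor(context_species2),
        acceptor_class_match=context_species1.acceptor_dinucleotide.upper()
        == context_species2.acceptor_dinucleotide.upper(),
        species_order=species_order,
    )
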