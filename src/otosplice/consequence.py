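"""Protein consequences of splice events: in-frame deletions vs frameshifts.

The constitutive and alternative coding sequences are both translated with
the standard genetic code.  Classification follows the removed nucleotide
count within the CDS: a multiple of 3 gives an in-frame deletion, anything
else shifts the reading frame, and translation of the shifted frame runs
to its first stop codon (or the transcript end, flagged ``stop_lost``).

Deleted residue ranges are reported left-aligned — the first residue at
which the two protein strings diverge — so that repeated flanking residues
cannot make the range ambiguous.  ``frameshift_start_aa`` is likewise the
first altered residue.

The module also computes spliced-isoform length ratios, global C-terminal
homology (percent identity/similarity under BLOSUM62) and peptide charge
profiles (Henderson-Hasselbalch net charge, isoelectric point by
bisection) used to characterise the truncated TMIEB-like products.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

from Bio import Align
from Bio.Align import substitution_matrices

from .events import SpliceEvent
from .model import GenomicInterval, ModelError, TranscriptModel, translate


class EventApplicationError(ValueError):
    """The event's junctions are inconsistent with the transcript."""


@dataclass(frozen=True)
class ProteinConsequence:
    event_id: str
    kind: str  # in_frame_deletion | frameshift | no_coding_change
    nt_removed: int
    product_length_aa: int
    deleted_aa_start: Optional[int] = None
    deleted_aa_end: Optional[int] = None
    frameshift_start_aa: Optional[int] = None
    novel_cterm_peptide: Optional[str] = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class IsoformLengthReport:
    constitutive_transcript_nt: int
    alternative_transcript_nt: int
    length_ratio: float  # alternative / constitutive, 3 decimals


@dataclass(frozen=True)
class HomologyReport:
    percent_identity: float
    percent_similarity: float
    aligned_length: int
    score: float
    alignment: str


@dataclass(frozen=True)
class PeptideChargeProfile:
    net_charge_pH7: float
    isoelectric_point: float


# ---------------------------------------------------------------------------
# Isoform construction
# ---------------------------------------------------------------------------

def _events_in_transcript_order(
    transcript: TranscriptModel, events: Sequence[SpliceEvent]
) -> list[SpliceEvent]:
    def pos(ev: SpliceEvent) -> int:
        r = ev.affected_region
        p = r.start if transcript.strand == "+" else r.end
        return transcript.genomic_to_spliced(p)

    ordered = sorted(events, key=pos)
    for a, b in zip(ordered, ordered[1:]):
        if a.affected_region.overlaps(b.affected_region):
            raise EventApplicationError(
                f"events {a.event_id} and {b.event_id} affect overlapping regions"
            )
    return ordered


def apply_event(
    transcript: TranscriptModel,
    event: Union[SpliceEvent, Sequence[SpliceEvent]],
) -> TranscriptModel:
    """Build the alternative isoform's transcript model.

    Accepts one event or a list, applied 5'->3' (overlapping events are
    rejected).  Exon skipping removes the skipped exon; an alternative 3'
    (5') splice site moves the downstream (upstream) exon boundary to the
    alternative acceptor (donor).  An event with an empty alternative
    junction set leaves the transcript unchanged.
    """
    events = list(event) if isinstance(event, (list, tuple)) else [event]
    events = [ev for ev in events if ev.alternative_junctions]
    if not events:
        return transcript
    events = _events_in_transcript_order(transcript, events)

    exons = list(transcript.exons)
    strand = transcript.strand
    for ev in events:
        aj = ev.alternative_junctions[0]
        if aj.interval.chrom != transcript.chrom or aj.interval.strand != strand:
            raise EventApplicationError(
                f"junction {aj.key} is not on the transcript's chromosome/strand"
            )
        if ev.event_type == "exon_skipping":
            region = ev.affected_region
            match = [
                i
                for i, e in enumerate(exons)
                if e.start == region.start and e.end == region.end
            ]
            if not match:
                raise EventApplicationError(
                    f"no exon matches skipped region for junction {aj.key}"
                )
            del exons[match[0]]
        elif ev.event_type == "alt_3ss":
            cj = ev.constitutive_junctions[0].interval
            # downstream exon starts right after the annotated intron
            if strand == "+":
                idx = [i for i, e in enumerate(exons) if e.start == cj.end + 1]
            else:
                idx = [i for i, e in enumerate(exons) if e.end == cj.start - 1]
            if not idx:
                raise EventApplicationError(
                    f"no exon abuts the constitutive acceptor of junction {aj.key}"
                )
            e = exons[idx[0]]
            if strand == "+":
                new = GenomicInterval(e.chrom, aj.interval.end + 1, e.end, strand)
            else:
                new = GenomicInterval(e.chrom, e.start, aj.interval.start - 1, strand)
            exons[idx[0]] = new
        elif ev.event_type == "alt_5ss":
            cj = ev.constitutive_junctions[0].interval
            if strand == "+":
                idx = [i for i, e in enumerate(exons) if e.end == cj.start - 1]
            else:
                idx = [i for i, e in enumerate(exons) if e.start == cj.end + 1]
            if not idx:
                raise EventApplicationError(
                    f"no exon abuts the constitutive donor of junction {aj.key}"
                )
            e = exons[idx[0]]
            if strand == "+":
                new = GenomicInterval(e.chrom, e.start, aj.interval.start - 1, strand)
            else:
                new = GenomicInterval(e.chrom, aj.interval.end + 1, e.end, strand)
            exons[idx[0]] = new
        else:
            raise EventApplicationError(
                f"cannot build an isoform for event type {ev.event_type!r}"
            )

    def inside(pos: Optional[int]) -> Optional[int]:
        if pos is None:
            return None
        return pos if any(e.contains(pos) for e in exons) else None

    cds_start = inside(transcript.cds_start)
    cds_end = inside(transcript.cds_end)
    if cds_start is None:
        cds_end = None
    elif cds_end is None:
        # stop position spliced out; anchor the provisional CDS end at the
        # transcript 3' terminus (re-translation decides the real stop)
        last = exons[-1]
        cds_end = last.end if strand == "+" else last.start
    suffix = "+".join(ev.event_id.split(":")[1] for ev in events)
    return TranscriptModel(
        transcript_id=f"{transcript.transcript_id}|{suffix}",
        gene_id=transcript.gene_id,
        exons=tuple(exons),
        cds_start=cds_start,
        cds_end=cds_end,
        sequence_source=transcript.sequence_source,
    )


# ---------------------------------------------------------------------------
# Consequence annotation
# ---------------------------------------------------------------------------

def _cds_overlap(region: GenomicInterval, transcript: TranscriptModel) -> int:
    """Exonic nucleotides of ``region`` that fall inside the CDS span."""
    lo = min(transcript.cds_start, transcript.cds_end)
    hi = max(transcript.cds_start, transcript.cds_end)
    total = 0
    for e in transcript.exons:
        s = max(e.start, region.start, lo)
        t = min(e.end, region.end, hi)
        if s <= t:
            total += t - s + 1
    return total


def annotate_consequence(
    transcript: TranscriptModel,
    event: SpliceEvent,
    genome: Mapping[str, str],
) -> ProteinConsequence:
    """Derive the protein-level consequence of one splice event.

    The constitutive protein is translated from the annotated CDS; the
    alternative isoform is rebuilt with :func:`apply_event` and re-translated
    from the (unchanged) start codon to the first stop in its frame.
    """
    if transcript.cds_start is None:
        raise ModelError(f"transcript {transcript.transcript_id} has no CDS")
    p_const = transcript.protein(genome)

    alt = apply_event(transcript, event)
    if alt.cds_start is None:
        raise EventApplicationError(
            f"event {event.event_id} removes the start codon of "
            f"{transcript.transcript_id}"
        )
    alt_spliced = alt.spliced_sequence(genome)
    start_off = alt.genomic_to_spliced(transcript.cds_start) - 1
    orf = alt_spliced[start_off:]
    p_alt_full = translate(orf)
    flags: list[str] = []
    if "*" in p_alt_full:
        p_alt = p_alt_full[: p_alt_full.index("*")]
    else:
        p_alt = p_alt_full
        flags.append("stop_lost")

    nt_removed = _cds_overlap(event.affected_region, transcript)

    if nt_removed == 0:
        return ProteinConsequence(
            event_id=event.event_id,
            kind="no_coding_change",
            nt_removed=0,
            product_length_aa=len(p_alt),
            flags=tuple(flags),
        )

    # first residue at which the two products diverge (left-aligned)
    div = next(
        (i for i, (a, b) in enumerate(zip(p_const, p_alt)) if a != b),
        min(len(p_const), len(p_alt)),
    )

    if nt_removed % 3 == 0:
        d = nt_removed // 3
        clean = (
            len(p_alt) == len(p_const) - d
            and p_alt[div:] == p_const[div + d :]
        )
        if clean:
            return ProteinConsequence(
                event_id=event.event_id,
                kind="in_frame_deletion",
                nt_removed=nt_removed,
                product_length_aa=len(p_alt),
                deleted_aa_start=div + 1,
                deleted_aa_end=div + d,
                flags=tuple(flags),
            )
        # junction not codon-aligned (or a new stop created): report the
        # affected codon span from geometry and flag the hybrid codon
        off = _cds_offset_of_region_start(transcript, event)
        first = off // 3 + 1
        last = (off + nt_removed - 1) // 3 + 1
        flags.append("hybrid_codon")
        if len(p_alt) < len(p_const) - d:
            flags.append("stop_gained")
        return ProteinConsequence(
            event_id=event.event_id,
            kind="in_frame_deletion",
            nt_removed=nt_removed,
            product_length_aa=len(p_alt),
            deleted_aa_start=first,
            deleted_aa_end=last,
            flags=tuple(flags),
        )

    return ProteinConsequence(
        event_id=event.event_id,
        kind="frameshift",
        nt_removed=nt_removed,
        product_length_aa=len(p_alt),
        frameshift_start_aa=div + 1,
        novel_cterm_peptide=p_alt[div:],
        flags=tuple(flags),
    )


def _cds_offset_of_region_start(
    transcript: TranscriptModel, event: SpliceEvent
) -> int:
    """0-based CDS offset of the first removed coding base."""
    region = event.affected_region
    cds_s, _ = transcript.cds_spliced_range()
    p5 = region.start if transcript.strand == "+" else region.end
    sp = transcript.genomic_to_spliced(p5)
    return max(sp, cds_s) - cds_s


def length_ratio(
    transcript_const: TranscriptModel, transcript_alt: TranscriptModel
) -> IsoformLengthReport:
    """Spliced-length ratio alternative/constitutive, to 3 decimals."""
    if transcript_const.gene_id != transcript_alt.gene_id:
        raise ValueError("length ratio is defined for isoforms of one gene")
    c = transcript_const.spliced_length
    a = transcript_alt.spliced_length
    return IsoformLengthReport(c, a, round(a / c, 3))


# ---------------------------------------------------------------------------
# C-terminal homology
# ---------------------------------------------------------------------------

def cterm_homology(
    peptide_a: str,
    peptide_b: str,
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> HomologyReport:
    """Global (Needleman-Wunsch) alignment of two peptides.

    Identity is the fraction of alignment columns with identical residues;
    similarity the fraction with a positive substitution score.  Gap
    columns count toward the denominator.
    """
    if not peptide_a or not peptide_b:
        raise ValueError("peptides must be non-empty")
    matrix = substitution_matrices.load(substitution_matrix)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(peptide_a, peptide_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    cols = len(row_a)
    ident = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    simil = sum(
        1
        for x, y in zip(row_a, row_b)
        if x != "-" and y != "-" and matrix[x, y] > 0
    )
    return HomologyReport(
        percent_identity=100.0 * ident / cols,
        percent_similarity=100.0 * simil / cols,
        aligned_length=cols,
        score=float(aln.score),
        alignment=f"{row_a}\n{row_b}",
    )


# ---------------------------------------------------------------------------
# Peptide charge
# ---------------------------------------------------------------------------

# EMBOSS pKa values
_PKA_POS = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
_PKA_NEG = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def net_charge(peptide: str, pH: float) -> float:
    """Henderson-Hasselbalch net charge at the given pH (EMBOSS pKa set)."""
    bad = set(peptide) - _STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    pos = 1.0 / (1.0 + 10 ** (pH - _PKA_POS["Nterm"]))
    neg = 1.0 / (1.0 + 10 ** (_PKA_NEG["Cterm"] - pH))
    for aa in peptide:
        if aa in _PKA_POS:
            pos += 1.0 / (1.0 + 10 ** (pH - _PKA_POS[aa]))
        elif aa in _PKA_NEG:
            neg += 1.0 / (1.0 + 10 ** (_PKA_NEG[aa] - pH))
    return pos - neg


def charge_profile(peptide: str, tol: float = 1e-4) -> PeptideChargeProfile:
    """Net charge at pH 7 and isoelectric point (bisection on [0, 14])."""
    lo, hi = 0.0, 14.0
    f_lo = net_charge(peptide, lo)
    mid = 7.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        f_mid = net_charge(peptide, mid)
        if abs(f_mid) < tol:
            break
        if (f_mid > 0) == (f_lo > 0):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return PeptideChargeProfile(
        net_charge_pH7=net_charge(peptide, 7.0),
        isoelectric_point=mid,
    )
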