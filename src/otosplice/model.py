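"""Core genomic data model.

Coordinate convention: 1-based, inclusive on both ends (GTF style),
everywhere in the package.  Splice junctions are stored as *intron*
intervals: ``start`` is the first intronic base and ``end`` the last.
Inputs in other conventions (0-based half-open BED) are converted at the
parser boundary in :mod:`otosplice.io`.

Strand convention: the donor site of an intron is the end adjacent to the
upstream exon in transcript orientation; on the minus strand this is the
*higher* genomic coordinate.  All reported dinucleotides are given in
transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

STRANDS = ("+", "-")

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_RC)[::-1]


class ModelError(ValueError):
    """Raised when a genomic object violates its structural invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval on one strand of a chromosome (1-based, inclusive)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ModelError("chrom must be non-empty")
        if self.strand not in STRANDS:
            raise ModelError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ModelError(
                f"require 1 <= start <= end, got {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def sequence(self, genome: Mapping[str, str]) -> str:
        """Strand-oriented sequence of this interval (upper case)."""
        raw = genome[self.chrom][self.start - 1 : self.end].upper()
        if len(raw) != self.length:
            raise ModelError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds sequence bounds"
            )
        return reverse_complement(raw) if self.strand == "-" else raw


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` are ordered 5'->3' in *transcript* orientation (descending
    genomic coordinates on the minus strand).  ``cds_start`` is the genomic
    coordinate of the first base of the start codon and ``cds_end`` the last
    base of the stop codon; on the minus strand ``cds_start > cds_end``.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    sequence_source: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ModelError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ModelError("all exons must share chrom and strand")
        for prev, nxt in zip(self.exons, self.exons[1:]):
            ok = nxt.start > prev.end if self.strand == "+" else nxt.end < prev.start
            if not ok:
                raise ModelError(
                    f"exons of {self.transcript_id} overlap or are out of "
                    "transcript order"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ModelError("cds_start and cds_end must be set together")
        if self.cds_start is not None:
            for pos in (self.cds_start, self.cds_end):
                if not any(e.contains(pos) for e in self.exons):
                    raise ModelError(
                        f"CDS boundary {pos} of {self.transcript_id} falls "
                        "outside all exons"
                    )

    # -- basic geometry ---------------------------------------------------
    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, lo, hi, self.strand)

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    def introns(self) -> tuple[GenomicInterval, ...]:
        """Introns in transcript order (donor side first)."""
        out = []
        for up, down in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(GenomicInterval(self.chrom, up.end + 1, down.start - 1, "+"))
            else:
                out.append(GenomicInterval(self.chrom, down.end + 1, up.start - 1, "-"))
        return tuple(out)

    # -- coordinate mapping -----------------------------------------------
    def genomic_to_spliced(self, pos: int) -> int:
        """Map a genomic position inside an exon to a 1-based spliced position."""
        acc = 0
        for e in self.exons:
            if e.contains(pos):
                off = pos - e.start + 1 if self.strand == "+" else e.end - pos + 1
                return acc + off
            acc += e.length
        raise ModelError(
            f"position {pos} is not exonic in transcript {self.transcript_id}"
        )

    def spliced_to_genomic(self, pos: int) -> int:
        if not (1 <= pos <= self.spliced_length):
            raise ModelError(f"spliced position {pos} out of range")
        acc = 0
        for e in self.exons:
            if pos <= acc + e.length:
                off = pos - acc
                return e.start + off - 1 if self.strand == "+" else e.end - off + 1
            acc += e.length
        raise AssertionError("unreachable")

    # -- sequence ---------------------------------------------------------
    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        return "".join(e.sequence(genome) for e in self.exons)

    def cds_spliced_range(self) -> tuple[int, int]:
        if self.cds_start is None:
            raise ModelError(f"transcript {self.transcript_id} has no CDS")
        s = self.genomic_to_spliced(self.cds_start)
        e = self.genomic_to_spliced(self.cds_end)
        if s > e:
            raise ModelError("CDS start maps 3' of CDS end; check strand convention")
        return s, e

    def cds_sequence(self, genome: Mapping[str, str]) -> str:
        s, e = self.cds_spliced_range()
        return self.spliced_sequence(genome)[s - 1 : e]

    def protein(self, genome: Mapping[str, str]) -> str:
        """Translate the CDS (standard code); returns residues without the stop.

        Raises :class:`ModelError` if the CDS length is not a codon multiple,
        does not start with ATG, or does not end with a stop codon.
        """
        cds = self.cds_sequence(genome)
        if len(cds) % 3 != 0:
            raise ModelError(
                f"CDS of {self.transcript_id} has length {len(cds)}, not a "
                "multiple of 3"
            )
        prot = translate(cds)
        if not prot.startswith("M") or not prot.endswith("*"):
            raise ModelError(
                f"CDS of {self.transcript_id} does not span ATG..stop"
            )
        if "*" in prot[:-1]:
            raise ModelError(f"internal stop codon in {self.transcript_id}")
        return prot[:-1]


# Standard genetic code (table 1); no selenocysteine handling.
_CODON_TABLE = {}


def _build_codon_table() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    _CODON_TABLE.update(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        _CODON_TABLE[stop] = "*"


_build_codon_table()

STOP_CODONS = frozenset(c for c, aa in _CODON_TABLE.items() if aa == "*")


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string; trailing partial codon dropped."""
    seq = seq.upper()
    return "".join(
        _CODON_TABLE.get(seq[i : i + 3], "X")
        for i in range(0, len(seq) - len(seq) % 3, 3)
    )


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcript models and a designated canonical one."""

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]
    canonical_transcript_id: str

    def __post_init__(self) -> None:
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ModelError(f"duplicate transcript ids in gene {self.gene_id}")
        if self.canonical_transcript_id not in ids:
            raise ModelError(
                f"canonical transcript {self.canonical_transcript_id} not found "
                f"in gene {self.gene_id}"
            )

    @property
    def canonical_transcript(self) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == self.canonical_transcript_id:
                return t
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class Junction:
    """A splice junction, stored as the intron interval it excises."""

    interval: GenomicInterval
    donor_dinucleotide: Optional[str] = None
    acceptor_dinucleotide: Optional[str] = None

    def __post_init__(self) -> None:
        if self.donor_dinucleotide is not None or self.acceptor_dinucleotide is not None:
            if self.interval.length < 4:
                raise ModelError(
                    "intron shorter than 4 nt cannot carry donor and acceptor "
                    "dinucleotides"
                )
            for d in (self.donor_dinucleotide, self.acceptor_dinucleotide):
                if d is not None and len(d) != 2:
                    raise ModelError(f"dinucleotide must have length 2, got {d!r}")

    @classmethod
    def from_interval(
        cls, interval: GenomicInterval, genome: Mapping[str, str]
    ) -> "Junction":
        """Build a junction with dinucleotides read from the genome."""
        seq = interval.sequence(genome)  # transcript orientation
        return cls(interval, donor_dinucleotide=seq[:2], acceptor_dinucleotide=seq[-2:])

    @property
    def key(self) -> tuple[str, int, int, str]:
        iv = self.interval
        return (iv.chrom, iv.start, iv.end, iv.strand)

    @property
    def donor_pos(self) -> int:
        """Genomic coordinate of the first intronic base on the donor side."""
        return self.interval.start if self.interval.strand == "+" else self.interval.end

    @property
    def acceptor_pos(self) -> int:
        """Genomic coordinate of the last intronic base on the acceptor side."""
        return self.interval.end if self.interval.strand == "+" else self.interval.start


class JunctionTable:
    """Per-group, per-replicate unique-read counts for splice junctions.

    Thin wrapper over a pandas DataFrame with columns
    ``chrom,start,end,strand,group,replicate,count``; one row per
    (junction, group, replicate).
    """

    COLUMNS = ("chrom", "start", "end", "strand", "group", "replicate", "count")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ModelError(f"junction table missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        df["count"] = df["count"].astype(int)
        df["replicate"] = df["replicate"].astype(str)
        df["group"] = df["group"].astype(str)
        if (df["count"] < 0).any():
            raise ModelError("negative junction counts")
        if not df["strand"].isin(STRANDS).all():
            raise ModelError("junction strand must be '+' or '-'")
        keys = ["chrom", "start", "end", "strand", "group", "replicate"]
        if df.duplicated(subset=keys).any():
            raise ModelError("duplicate (junction, group, replicate) rows")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "JunctionTable":
        """Records of (Junction|GenomicInterval, group, replicate, count)."""
        rows = []
        for junc, group, replicate, count in records:
            iv = junc.interval if isinstance(junc, Junction) else junc
            rows.append(
                dict(
                    chrom=iv.chrom,
                    start=iv.start,
                    end=iv.end,
                    strand=iv.strand,
                    group=group,
                    replicate=replicate,
                    count=count,
                )
            )
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, JunctionTable):
            return NotImplemented
        key = ["chrom", "start", "end", "strand", "group", "replicate"]
        a = self.df.sort_values(key).reset_index(drop=True)
        b = other.df.sort_values(key).reset_index(drop=True)
        return a.equals(b)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["group"].unique()))

    @property
    def replicates(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["replicate"].unique()))

    def junctions(self) -> tuple[GenomicInterval, ...]:
        """Distinct junction intervals, sorted genomically."""
        uniq = (
            self.df[["chrom", "start", "end", "strand"]]
            .drop_duplicates()
            .sort_values(["chrom", "start", "end", "strand"])
        )
        return tuple(
            GenomicInterval(r.chrom, r.start, r.end, r.strand)
            for r in uniq.itertuples()
        )

    def subset(self, chrom: str, strand: str, start: int, end: int) -> "JunctionTable":
        """Rows whose junction lies within [start, end] on chrom/strand."""
        m = (
            (self.df["chrom"] == chrom)
            & (self.df["strand"] == strand)
            & (self.df["start"] >= start)
            & (self.df["end"] <= end)
        )
        return JunctionTable(self.df[m])

    def pooled_count(self, interval: GenomicInterval, group: Optional[str] = None) -> int:
        m = (
            (self.df["chrom"] == interval.chrom)
            & (self.df["start"] == interval.start)
            & (self.df["end"] == interval.end)
            & (self.df["strand"] == interval.strand)
        )
        if group is not None:
            m &= self.df["group"] == group
        return int(self.df.loc[m, "count"].sum())

    def replicate_counts(
        self, interval: GenomicInterval, group: Optional[str] = None
    ) -> dict[str, int]:
        """Per-replicate counts (summed over groups unless one is given)."""
        m = (
            (self.df["chrom"] == interval.chrom)
            & (self.df["start"] == interval.start)
            & (self.df["end"] == interval.end)
            & (self.df["strand"] == interval.strand)
        )
        if group is not None:
            m &= self.df["group"] == group
        sub = self.df.loc[m]
        return {str(k): int(v) for k, v in sub.groupby("replicate")["count"].sum().items()}

    def support_replicates(self, interval: GenomicInterval) -> int:
        """Max over groups of the number of replicates with count > 0."""
        best = 0
        for g in self.groups:
            counts = self.replicate_counts(interval, group=g)
            best = max(best, sum(1 for c in counts.values() if c > 0))
        return best

    @classmethod
    def concat(cls, tables: Sequence["JunctionTable"]) -> "JunctionTable":
        if not tables:
            return cls(pd.DataFrame(columns=list(cls.COLUMNS)))
        return cls(pd.concat([t.df for t in tables], ignore_index=True))
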