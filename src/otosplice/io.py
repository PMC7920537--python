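"""Readers and writers: GTF gene models, FASTA, junction tables, reports.

Junction-count input dialects:

* ``star_sj`` — the 9-column ``SJ.out.tab`` TSV written by spliced aligners
  (chrom, intron start, intron end, strand code 0/1/2, motif code,
  annotated flag, unique reads, multimapped reads, max overhang); intron
  coordinates are 1-based inclusive and are kept as-is.
* ``bed_intron`` — BED6 of intron intervals (0-based half-open, score =
  unique reads); converted to 1-based inclusive at this boundary.

Group/replicate labels are never guessed from filenames: a manifest TSV
with columns ``file, group, replicate`` is required.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .model import (
    GeneModel,
    GenomicInterval,
    JunctionTable,
    TranscriptModel,
)

DIALECTS = ("star_sj", "bed_intron")

_STAR_STRAND = {"0": "+", "1": "+", "2": "-"}  # 0 (undefined) defaults to '+'
_MOTIF_CODE = {("GT", "AG"): 1, ("CT", "AC"): 2, ("GC", "AG"): 3,
               ("CT", "GC"): 4, ("AT", "AC"): 5, ("GT", "AT"): 6}


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _prevalidate_gtf(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if fields[6] not in ("+", "-", "."):
                raise ParseError(f"{path}:{lineno}: bad strand {fields[6]!r}")


def read_gtf(path) -> list[GeneModel]:
    """Read an Ensembl-dialect GTF into :class:`GeneModel` objects.

    Exon and CDS features are grouped per transcript; a ``gene`` feature
    may carry a ``canonical_transcript_id`` attribute (written by
    :func:`write_gtf`); otherwise the first transcript is canonical.
    Transcripts without exon features are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_gtf(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    gene_of: dict[str, str] = {}
    canonical: dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype == "gene":
            gid = feat.attributes.get("gene_id", [feat.id])[0]
            if "canonical_transcript_id" in feat.attributes:
                canonical[gid] = feat.attributes["canonical_transcript_id"][0]
            continue
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gene_of[tid] = feat.attributes.get("gene_id", ["."])[0]
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(feat)

    transcripts: dict[str, list[TranscriptModel]] = {}
    for tid, gid in gene_of.items():
        feats = exons.get(tid)
        if not feats:
            warnings.warn(f"transcript {tid} has no exon features; skipped")
            continue
        strand = feats[0].strand
        ivs = sorted(
            (GenomicInterval(f.seqid, f.start, f.end, strand) for f in feats),
            key=lambda iv: iv.start,
            reverse=(strand == "-"),
        )
        cds_start = cds_end = None
        if tid in cds:
            lo = min(f.start for f in cds[tid])
            hi = max(f.end for f in cds[tid])
            cds_start, cds_end = (lo, hi) if strand == "+" else (hi, lo)
        tm = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            exons=tuple(ivs),
            cds_start=cds_start,
            cds_end=cds_end,
            sequence_source=feats[0].seqid,
        )
        transcripts.setdefault(gid, []).append(tm)

    genes = []
    for gid, txs in transcripts.items():
        txs = sorted(txs, key=lambda t: t.transcript_id)
        canon = canonical.get(gid, txs[0].transcript_id)
        genes.append(GeneModel(gid, tuple(txs), canon))
    return sorted(genes, key=lambda g: g.gene_id)


def write_gtf(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as Ensembl-dialect GTF (CDS includes the stop codon)."""
    lines = []
    for gene in genes:
        span_lo = min(t.span.start for t in gene.transcripts)
        span_hi = max(t.span.end for t in gene.transcripts)
        strand = gene.transcripts[0].strand
        chrom = gene.transcripts[0].chrom
        attrs = (
            f'gene_id "{gene.gene_id}"; '
            f'canonical_transcript_id "{gene.canonical_transcript_id}";'
        )
        lines.append(
            f"{chrom}\totosplice\tgene\t{span_lo}\t{span_hi}\t.\t{strand}\t.\t{attrs}"
        )
        for tx in gene.transcripts:
            tattrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
            sp = tx.span
            lines.append(
                f"{chrom}\totosplice\ttranscript\t{sp.start}\t{sp.end}\t.\t"
                f"{strand}\t.\t{tattrs}"
            )
            for e in sorted(tx.exons, key=lambda iv: iv.start):
                lines.append(
                    f"{chrom}\totosplice\texon\t{e.start}\t{e.end}\t.\t"
                    f"{strand}\t.\t{tattrs}"
                )
            if tx.cds_start is not None:
                lo = min(tx.cds_start, tx.cds_end)
                hi = max(tx.cds_start, tx.cds_end)
                for e in sorted(tx.exons, key=lambda iv: iv.start):
                    s, t = max(e.start, lo), min(e.end, hi)
                    if s <= t:
                        lines.append(
                            f"{chrom}\totosplice\tCDS\t{s}\t{t}\t.\t{strand}\t.\t{tattrs}"
                        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Multi-record FASTA to a name->sequence mapping (upper-cased)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"duplicate FASTA record name {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Junction tables
# ---------------------------------------------------------------------------

def read_manifest(path) -> pd.DataFrame:
    """Manifest TSV with columns file, group, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"file", "group", "replicate"}
    if not need <= set(df.columns):
        raise ParseError(f"manifest {path} must have columns {sorted(need)}")
    return df


def _read_star_sj(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(f)}")
            count = int(f[6])
            if count < 0:
                raise ParseError(f"{path}:{lineno}: negative unique-read count")
            rows.append(
                dict(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=_STAR_STRAND.get(f[3], "+"),
                    count=count,
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "count"])


def _read_bed_intron(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected BED6, got {len(f)} columns")
            count = int(f[4])
            if count < 0:
                raise ParseError(f"{path}:{lineno}: negative count")
            rows.append(
                dict(
                    chrom=f[0],
                    start=int(f[1]) + 1,  # 0-based half-open -> 1-based inclusive
                    end=int(f[2]),
                    strand=f[5],
                    count=count,
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "count"])


def read_junction_table(manifest_path, dialect: str = "star_sj") -> JunctionTable:
    """Read per-replicate junction files listed in a manifest into one table.

    File paths in the manifest are resolved relative to the manifest's
    directory unless absolute.
    """
    if dialect not in DIALECTS:
        raise ParseError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    reader = _read_star_sj if dialect == "star_sj" else _read_bed_intron
    frames = []
    for row in manifest.itertuples():
        p = Path(row.file)
        if not p.is_absolute():
            p = manifest_path.parent / p
        df = reader(p)
        df["group"] = row.group
        df["replicate"] = row.replicate
        frames.append(df)
    if not frames:
        return JunctionTable(pd.DataFrame(columns=list(JunctionTable.COLUMNS)))
    return JunctionTable(pd.concat(frames, ignore_index=True))


def write_junction_table(table: JunctionTable, outdir, prefix: str = "sj") -> Path:
    """Write one star_sj file per (group, replicate) plus a manifest TSV.

    Returns the manifest path, suitable for :func:`read_junction_table`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for (group, rep), sub in sorted(table.df.groupby(["group", "replicate"])):
        fname = f"{prefix}_{group}_rep{rep}.tab"
        with open(outdir / fname, "w") as fh:
            for r in sub.sort_values(["chrom", "start", "end"]).itertuples():
                strand_code = 1 if r.strand == "+" else 2
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{strand_code}\t0\t0\t"
                    f"{r.count}\t0\t50\n"
                )
        records.append(dict(file=fname, group=group, replicate=rep))
    manifest = outdir / f"{prefix}_manifest.tsv"
    pd.DataFrame(records, columns=["file", "group", "replicate"]).to_csv(
        manifest, sep="\t", index=False
    )
    return manifest


# ---------------------------------------------------------------------------
# Events / reports
# ---------------------------------------------------------------------------

EVENTS_TSV_COLUMNS = (
    "event_id",
    "gene_id",
    "event_type",
    "chrom",
    "strand",
    "affected_start",
    "affected_end",
    "constitutive_junctions",
    "alternative_junctions",
)


def _fmt_junctions(junctions) -> str:
    return ";".join(f"{j.interval.start}-{j.interval.end}" for j in junctions)


def write_events_tsv(events, path) -> None:
    """Stable TSV of splice events; an empty list yields a header-only file."""
    lines = ["\t".join(EVENTS_TSV_COLUMNS)]
    for ev in events:
        lines.append(
            "\t".join(
                [
                    ev.event_id,
                    ev.gene_id,
                    ev.event_type,
                    ev.affected_region.chrom,
                    ev.affected_region.strand,
                    str(ev.affected_region.start),
                    str(ev.affected_region.end),
                    _fmt_junctions(ev.constitutive_junctions),
                    _fmt_junctions(ev.alternative_junctions),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_events_tsv(path):
    """Round-trip reader for :func:`write_events_tsv` (dinucleotides not stored)."""
    from .events import SpliceEvent
    from .model import Junction

    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        return []
    events = []
    for r in df.itertuples():
        def juncs(spec: str):
            out = []
            for part in str(spec).split(";"):
                if not part or part == "nan":
                    continue
                s, e = part.split("-")
                out.append(
                    Junction(GenomicInterval(r.chrom, int(s), int(e), r.strand))
                )
            return tuple(out)

        events.append(
            SpliceEvent(
                event_id=r.event_id,
                gene_id=r.gene_id,
                event_type=r.event_type,
                constitutive_junctions=juncs(r.constitutive_junctions),
                alternative_junctions=juncs(r.alternative_junctions),
                affected_region=GenomicInterval(
                    r.chrom, int(r.affected_start), int(r.affected_end), r.strand
                ),
            )
        )
    return events


def write_report_json(report: Mapping, path) -> None:
    """Deterministic JSON report (sorted keys, trailing newline)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    import dataclasses

    import numpy as np

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
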