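"""Synthetic gene models, junction-count simulations, and CT simulations.

Three named fixtures mirror the event geometries of the Tmc1/Lhfpl5/Tmie
splice isoforms:

* ``tmc1_like`` — a 16-exon, 4,000-nt transcript (760-codon CDS) whose
  ninth exon spans codons 213-245 exactly (99 nt, so skipping it deletes
  that 33-aa block) and whose fourteenth exon carries an alternative 3'
  acceptor 9 nt downstream, deleting codons 521-523;
* ``lhfpl5_like`` — a 3-exon, 1,275-nt transcript (219-codon CDS) with a
  GC-donor first intron and an alternative acceptor 153 nt into exon 2,
  deleting codons 166-216;
* ``tmie_like`` — a 5-exon, 667-nt minus-strand transcript (153-codon CDS)
  with an alternative acceptor 8 nt into exon 4, shifting the reading
  frame from codon 61; the downstream sequence is engineered so the
  shifted frame yields 67 novel residues before its stop (127-aa product).

Sequence fill is random but constraint-checked: required splice-site
dinucleotides, stop-codon placement, junction-context bases that make the
overhang-2 discriminating primer carry exactly one 3'-terminal mismatch
against the constitutive isoform, and distinct residues at deletion
boundaries so deleted ranges are unambiguous.

Isoform mixtures default to the study conditions: 5% alternative for the
Tmc1-like and Tmie-like events (the ~95:5 ratios) and 7% for the
Lhfpl5-like event (~93:7), with 10,000 junction reads per event, five
replicates, and IHC/OHC as the two cell-type groups.  CT simulation uses
a 2-fold basal/apical gradient with 0.2-cycle Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .events import SpliceEvent
from .model import (
    GeneModel,
    GenomicInterval,
    Junction,
    JunctionTable,
    STOP_CODONS,
    TranscriptModel,
    reverse_complement,
    translate,
)
from .qpcr import CtRecord, SEGMENTS

DEFAULT_SEED = 20210223

_BASES = "ACGT"


class FixtureConstraintError(RuntimeError):
    """Constraint satisfaction failed after bounded retries."""


@dataclass(frozen=True)
class EventSpec:
    """Definition of one engineered splice event within a fixture."""

    name: str
    kind: str  # exon_skipping | alt_3ss
    true_alt_fraction: float
    exon_index: Optional[int] = None      # 1-based, exon_skipping
    intron_index: Optional[int] = None    # 1-based, alt_3ss (intron 5' of the exon)
    shift_nt: Optional[int] = None        # nt the acceptor moves into the exon
    frameshift_novel_aa: Optional[int] = None  # engineered novel residues before stop


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    chrom: str
    strand: str
    exon_lengths: tuple[int, ...]
    utr5: int
    cds_codons: int           # protein length in residues (stop codon extra)
    events: tuple[EventSpec, ...]
    intron_length: int = 200
    base_constraints: Mapping[int, str] = field(default_factory=dict)  # spliced pos -> allowed
    distinct_aa_pairs: tuple[tuple[int, int], ...] = ()
    donor_overrides: Mapping[int, str] = field(default_factory=dict)   # intron idx -> dinuc
    pad: int = 50


@dataclass(frozen=True)
class Fixture:
    spec: FixtureSpec
    gene_model: GeneModel
    genome: dict[str, str]
    events: tuple[SpliceEvent, ...]
    mixtures: dict[str, float]  # event_id -> default alternative fraction

    @property
    def chrom(self) -> str:
        return self.spec.chrom


# ---------------------------------------------------------------------------
# Named fixture specifications
# ---------------------------------------------------------------------------

def _tmc1_like() -> FixtureSpec:
    # spliced layout: exon 9 = 737..835 (codons 213-245), exon 14 starts at
    # 1661 (codon 521); total 4,000 nt so the 108-nt double removal gives a
    # 0.973 length ratio.
    return FixtureSpec(
        name="tmc1_like",
        chrom="chr_tmc1_like",
        strand="+",
        exon_lengths=(150, 150, 120, 80, 60, 60, 60, 56, 99, 105, 160, 200, 360, 240, 300, 1800),
        utr5=100,
        cds_codons=760,
        events=(
            EventSpec(name="exon9_skip", kind="exon_skipping", exon_index=9,
                      true_alt_fraction=0.05),
            EventSpec(name="exon14_alt3ss", kind="alt_3ss", intron_index=13,
                      shift_nt=9, true_alt_fraction=0.05),
        ),
        # removed segment ends in the alternative acceptor AG (codon 523);
        # exon 13 ends (codon 520) differing at the -2 base only, so the
        # overhang-2 primer has one 3'-terminal mismatch vs the constitutive
        # template
        base_constraints={1668: "A", 1669: "G", 1659: "CGT", 1660: "G"},
        distinct_aa_pairs=((212, 245), (213, 246), (520, 523), (521, 524)),
    )


def _lhfpl5_like() -> FixtureSpec:
    # exon 2 starts at codon 166; alternative acceptor 153 nt in removes
    # codons 166-216; first intron carries the minor-canonical GC donor.
    return FixtureSpec(
        name="lhfpl5_like",
        chrom="chr_lhfpl5_like",
        strand="+",
        exon_lengths=(595, 300, 380),
        utr5=100,
        cds_codons=219,
        events=(
            EventSpec(name="exon2_alt3ss", kind="alt_3ss", intron_index=1,
                      shift_nt=153, true_alt_fraction=0.07),
        ),
        base_constraints={747: "A", 748: "G", 594: "CGT", 595: "G"},
        distinct_aa_pairs=((165, 216), (166, 217)),
        donor_overrides={1: "GC"},
    )


def _tmie_like() -> FixtureSpec:
    # minus-strand gene; exon 4 starts at codon 61 and the 8-nt removal
    # shifts the frame there; 67 engineered novel residues give a 127-aa
    # truncated product; 667-nt transcript yields the 0.988 length ratio.
    return FixtureSpec(
        name="tmie_like",
        chrom="chr_tmie_like",
        strand="-",
        exon_lengths=(120, 80, 30, 190, 247),
        utr5=50,
        cds_codons=153,
        events=(
            EventSpec(name="exon4_alt3ss", kind="alt_3ss", intron_index=3,
                      shift_nt=8, true_alt_fraction=0.05,
                      frameshift_novel_aa=67),
        ),
        base_constraints={237: "A", 238: "G", 229: "CGT", 230: "G"},
    )


PRESETS = {
    "tmc1_like": _tmc1_like,
    "lhfpl5_like": _lhfpl5_like,
    "tmie_like": _tmie_like,
}

FIXTURE_NAMES = tuple(PRESETS)


# ---------------------------------------------------------------------------
# Constrained sequence construction
# ---------------------------------------------------------------------------

def _choice(rng, allowed: str) -> str:
    return allowed[rng.integers(len(allowed))]


def _build_spliced(spec: FixtureSpec, rng) -> list[str]:
    """Random spliced sequence honouring base constraints and an open ORF."""
    total = sum(spec.exon_lengths)
    cds_len = 3 * (spec.cds_codons + 1)
    c1 = spec.utr5 + 1
    c2 = spec.utr5 + cds_len
    if c2 > total:
        raise FixtureConstraintError("CDS does not fit inside the spliced transcript")
    allowed = {p: spec.base_constraints.get(p, _BASES) for p in range(1, total + 1)}
    seq = [_choice(rng, allowed[p]) for p in range(1, total + 1)]

    def set_codon(idx: int, codon: str) -> None:  # idx 1-based codon number
        p = c1 + 3 * (idx - 1)
        for off, base in enumerate(codon):
            if base not in allowed[p + off]:
                raise FixtureConstraintError(
                    f"constraint at spliced position {p + off} conflicts with "
                    f"codon {idx} = {codon}"
                )
            seq[p + off - 1] = base

    def get_codon(idx: int) -> str:
        p = c1 + 3 * (idx - 1) - 1
        return "".join(seq[p : p + 3])

    def resample_codon(idx: int) -> None:
        p = c1 + 3 * (idx - 1)
        for _ in range(200):
            cand = "".join(_choice(rng, allowed[p + off]) for off in range(3))
            if cand not in STOP_CODONS:
                set_codon(idx, cand)
                return
        raise FixtureConstraintError(f"cannot avoid a stop at codon {idx}")

    set_codon(1, "ATG")
    for idx in range(2, spec.cds_codons + 1):
        if get_codon(idx) in STOP_CODONS:
            resample_codon(idx)
    set_codon(spec.cds_codons + 1, "TAA")

    for i, j in spec.distinct_aa_pairs:
        for _ in range(200):
            if translate(get_codon(i)) != translate(get_codon(j)):
                break
            resample_codon(j)
        else:
            raise FixtureConstraintError(f"cannot distinguish residues {i} and {j}")

    for ev in spec.events:
        if ev.kind == "alt_3ss" and ev.frameshift_novel_aa is not None:
            _engineer_frameshift(spec, seq, ev, rng)
    return seq


def _engineer_frameshift(spec: FixtureSpec, seq: list[str], ev: EventSpec, rng) -> None:
    """Shape the region downstream of the alternative acceptor so that the
    shifted frame carries exactly ``frameshift_novel_aa`` novel residues
    before a stop, while the constitutive frame keeps its ORF open."""
    c1 = spec.utr5 + 1
    cds_len = 3 * (spec.cds_codons + 1)
    exon_starts = np.cumsum((0,) + spec.exon_lengths[:-1]) + 1
    removal_start_sp = int(exon_starts[ev.intron_index])  # head of the downstream exon
    off0 = removal_start_sp - c1  # 0-based CDS offset of the first removed base
    if off0 % 3 != 0:
        raise FixtureConstraintError("frameshift engineering expects a codon-aligned removal start")
    shift = ev.shift_nt
    m = ev.frameshift_novel_aa
    d0 = off0 + shift                   # CDS offset where region D begins
    d_len = cds_len - d0
    if 3 * m + 3 > d_len:
        raise FixtureConstraintError("not enough downstream sequence for the engineered stop")
    alt_stop_at = 3 * m               # D-offset of the shifted-frame stop codon
    const_stop_at = d_len - 3          # D-offset of the constitutive stop

    base_at = lambda cds_off: seq[c1 - 1 + cds_off]

    def d_index_to_seq(i: int) -> int:  # 0-based index into seq
        return c1 - 1 + d0 + i

    const_codon_aa = translate("".join(base_at(off0 + k) for k in range(3)))

    for _ in range(100):
        forced: dict[int, str] = {}
        for k, b in enumerate("TGA"):
            forced[alt_stop_at + k] = b
        for k, b in enumerate("TAA"):
            forced[const_stop_at + k] = b
        ok = True
        for i in range(d_len):
            si = d_index_to_seq(i)
            pos = si + 1
            allow = spec.base_constraints.get(pos, _BASES)
            if i in forced:
                if forced[i] not in allow:
                    raise FixtureConstraintError("forced stop conflicts with a base constraint")
                seq[si] = forced[i]
            else:
                seq[si] = _choice(rng, allow)
            # shifted-frame codon completed at i?
            if (i + 1) % 3 == 0:
                k = (i + 1) // 3 - 1
                if k < m and "".join(seq[d_index_to_seq(i - 2) : si + 1]) in STOP_CODONS:
                    if i in forced:
                        ok = False
                        break
                    repl = [b for b in allow if b not in "AG"]
                    if not repl:
                        ok = False
                        break
                    seq[si] = _choice(rng, "".join(repl))
            # constitutive-frame codon completed at i?
            g = d0 + i
            if (g + 1) % 3 == 0 and g < cds_len - 3:
                codon = "".join(seq[c1 - 1 + g - 2 : c1 + g])
                if codon in STOP_CODONS:
                    if i in forced:
                        ok = False
                        break
                    repl = [b for b in allow if b not in "AG"]
                    if not repl:
                        ok = False
                        break
                    seq[si] = _choice(rng, "".join(repl))
        if not ok:
            continue
        alt_first = translate("".join(seq[d_index_to_seq(0) : d_index_to_seq(0) + 3]))
        if alt_first != const_codon_aa:
            return
    raise FixtureConstraintError("frameshift engineering failed after bounded retries")


# ---------------------------------------------------------------------------
# Layout -> genome
# ---------------------------------------------------------------------------

class _Layout:
    """Pre-mRNA layout (exons + introns, transcript orientation) and its
    mapping onto a padded genomic sequence on either strand."""

    def __init__(self, spec: FixtureSpec):
        self.spec = spec
        self.exon_layout: list[tuple[int, int]] = []
        pos = 1
        for i, L in enumerate(spec.exon_lengths):
            self.exon_layout.append((pos, pos + L - 1))
            pos += L
            if i < len(spec.exon_lengths) - 1:
                pos += spec.intron_length
        self.pre_len = pos - 1
        self.genome_len = self.pre_len + 2 * spec.pad

    def intron_layout(self, i: int) -> tuple[int, int]:  # 1-based intron index
        return (self.exon_layout[i - 1][1] + 1, self.exon_layout[i][0] - 1)

    def spliced_to_layout(self, sp: int) -> int:
        acc = 0
        for (a, b), L in zip(self.exon_layout, self.spec.exon_lengths):
            if sp <= acc + L:
                return a + (sp - acc) - 1
            acc += L
        raise ValueError(f"spliced position {sp} out of range")

    def to_genomic(self, layout_pos: int) -> int:
        if self.spec.strand == "+":
            return self.spec.pad + layout_pos
        return self.spec.pad + self.pre_len - layout_pos + 1

    def interval(self, layout_a: int, layout_b: int) -> GenomicInterval:
        ga, gb = self.to_genomic(layout_a), self.to_genomic(layout_b)
        return GenomicInterval(self.spec.chrom, min(ga, gb), max(ga, gb), self.spec.strand)


def _assemble(spec: FixtureSpec, spliced: list[str], rng) -> tuple[str, _Layout]:
    layout = _Layout(spec)
    pre = [""] * layout.pre_len
    acc = 0
    for (a, b), L in zip(layout.exon_layout, spec.exon_lengths):
        pre[a - 1 : b] = spliced[acc : acc + L]
        acc += L
    for i in range(1, len(spec.exon_lengths)):
        ia, ib = layout.intron_layout(i)
        donor = spec.donor_overrides.get(i, "GT")
        body = [_choice(rng, _BASES) for _ in range(ib - ia + 1 - 4)]
        pre[ia - 1 : ib] = list(donor) + body + ["A", "G"]
    pre_seq = "".join(pre)
    pad_l = "".join(_choice(rng, _BASES) for _ in range(spec.pad))
    pad_r = "".join(_choice(rng, _BASES) for _ in range(spec.pad))
    mid = pre_seq if spec.strand == "+" else reverse_complement(pre_seq)
    return pad_l + mid + pad_r, layout


def _build_events(
    spec: FixtureSpec, layout: _Layout, genome: Mapping[str, str], gene_id: str
) -> tuple[tuple[SpliceEvent, ...], dict[str, float]]:
    events, mixtures = [], {}
    for ev in spec.events:
        if ev.kind == "exon_skipping":
            e = ev.exon_index
            ia, ib = layout.intron_layout(e - 1)
            ja, jb = layout.intron_layout(e)
            alt_iv = layout.interval(ia, jb)
            const_ivs = [layout.interval(ia, ib), layout.interval(ja, jb)]
            region = layout.interval(*layout.exon_layout[e - 1])
        elif ev.kind == "alt_3ss":
            i = ev.intron_index
            ia, ib = layout.intron_layout(i)
            alt_iv = layout.interval(ia, ib + ev.shift_nt)
            const_ivs = [layout.interval(ia, ib)]
            ea, _ = layout.exon_layout[i]
            region = layout.interval(ea, ea + ev.shift_nt - 1)
        else:
            raise FixtureConstraintError(f"unsupported event kind {ev.kind!r}")
        event = SpliceEvent(
            event_id=f"{gene_id}:{ev.kind}:{region.chrom}:{region.start}-{region.end}",
            gene_id=gene_id,
            event_type=ev.kind,
            constitutive_junctions=tuple(
                Junction.from_interval(iv, genome) for iv in const_ivs
            ),
            alternative_junctions=(Junction.from_interval(alt_iv, genome),),
            affected_region=region,
        )
        events.append(event)
        mixtures[event.event_id] = ev.true_alt_fraction
    return tuple(events), mixtures


def _verify(spec: FixtureSpec, fixture: "Fixture") -> None:
    tx = fixture.gene_model.canonical_transcript
    tx.protein(fixture.genome)  # raises unless ATG..stop with a clean ORF
    spliced = tx.spliced_sequence(fixture.genome)
    for pos, allow in spec.base_constraints.items():
        if spliced[pos - 1] not in allow:
            raise FixtureConstraintError(f"base constraint violated at spliced {pos}")
    for i, iv in enumerate(tx.introns(), start=1):
        j = Junction.from_interval(iv, fixture.genome)
        want = spec.donor_overrides.get(i, "GT")
        if j.donor_dinucleotide != want or j.acceptor_dinucleotide != "AG":
            raise FixtureConstraintError(f"intron {i} dinucleotides not {want}..AG")
    c1 = spec.utr5 + 1
    cds = spliced[c1 - 1 : c1 - 1 + 3 * (spec.cds_codons + 1)]
    for ev in spec.events:
        if ev.kind != "alt_3ss":
            continue
        if ev.frameshift_novel_aa is not None:
            exon_starts = np.cumsum((0,) + spec.exon_lengths[:-1]) + 1
            off0 = int(exon_starts[ev.intron_index]) - c1
            alt_cds = cds[:off0] + cds[off0 + ev.shift_nt :]
            prot = translate(alt_cds)
            stop = prot.index("*")
            want = off0 // 3 + ev.frameshift_novel_aa
            if stop != want:
                raise FixtureConstraintError(
                    f"engineered frameshift product has {stop} aa, wanted {want}"
                )


def make_fixture(spec, seed: Optional[int] = None) -> Fixture:
    """Build a fixture from a named preset or a :class:`FixtureSpec`.

    Generation is seeded and deterministic; constraint satisfaction is
    retried with derived seeds a bounded number of times.
    """
    if isinstance(spec, str):
        try:
            spec = PRESETS[spec]()
        except KeyError:
            raise KeyError(
                f"unknown fixture {spec!r}; known: {sorted(PRESETS)}"
            ) from None
    if seed is None:
        seed = DEFAULT_SEED
    last_err: Optional[Exception] = None
    for attempt in range(20):
        rng = np.random.default_rng([seed, attempt])
        try:
            spliced = _build_spliced(spec, rng)
            genome_seq, layout = _assemble(spec, spliced, rng)
            genome = {spec.chrom: genome_seq}
            gene_id = spec.name.upper()
            exons = [layout.interval(a, b) for a, b in layout.exon_layout]
            if spec.strand == "-":
                exons = exons  # transcript order preserved: layout order is 5'->3'
            tx = TranscriptModel(
                transcript_id=f"{gene_id}_T1",
                gene_id=gene_id,
                exons=tuple(exons),
                cds_start=layout.to_genomic(layout.spliced_to_layout(spec.utr5 + 1)),
                cds_end=layout.to_genomic(
                    layout.spliced_to_layout(spec.utr5 + 3 * (spec.cds_codons + 1))
                ),
                sequence_source=spec.chrom,
            )
            gene = GeneModel(gene_id, (tx,), tx.transcript_id)
            events, mixtures = _build_events(spec, layout, genome, gene_id)
            fixture = Fixture(spec=spec, gene_model=gene, genome=genome,
                              events=events, mixtures=mixtures)
            _verify(spec, fixture)
            return fixture
        except FixtureConstraintError as err:
            last_err = err
    raise FixtureConstraintError(
        f"could not satisfy constraints for {spec.name} after 20 attempts: {last_err}"
    )


def make_all_fixtures(seed: Optional[int] = None) -> dict[str, Fixture]:
    return {name: make_fixture(name, seed=seed) for name in FIXTURE_NAMES}


# ---------------------------------------------------------------------------
# Random fixtures for property testing
# ---------------------------------------------------------------------------

def random_fixture_spec(rng) -> FixtureSpec:
    """A random small gene model carrying one random deletion-type event.

    Used for randomized agreement testing between the consequence engine
    and naive re-translation; no primer/dinucleotide engineering applied.
    """
    for _ in range(100):
        n_exons = int(rng.integers(4, 9))
        exon_lengths = tuple(int(rng.integers(60, 200)) for _ in range(n_exons))
        total = sum(exon_lengths)
        utr5 = int(rng.integers(20, 60))
        # leave room for a 3' UTR
        max_codons = (total - utr5 - 30) // 3 - 1
        cds_codons = int(rng.integers(40, max_codons))
        c1, c2 = utr5 + 1, utr5 + 3 * (cds_codons + 1)
        bounds = []
        acc = 0
        for L in exon_lengths:
            bounds.append((acc + 1, acc + L))
            acc += L
        interior = [
            i
            for i, (s, t) in enumerate(bounds)
            if 1 <= i <= n_exons - 2 and s > c1 + 3 and t < c2 - 3
        ]
        if not interior:
            continue
        if rng.random() < 0.5:
            e = int(rng.choice(interior))
            ev = EventSpec(name="rand_skip", kind="exon_skipping",
                           exon_index=e + 1, true_alt_fraction=0.1)
        else:
            e = int(rng.choice(interior))
            s, t = bounds[e]
            max_shift = min(40, t - s - 10)
            if max_shift < 1:
                continue
            shift = int(rng.integers(1, max_shift + 1))
            ev = EventSpec(name="rand_alt3ss", kind="alt_3ss",
                           intron_index=e, shift_nt=shift, true_alt_fraction=0.1)
        strand = "+" if rng.random() < 0.5 else "-"
        return FixtureSpec(
            name="rand_fixture",
            chrom="chr_rand",
            strand=strand,
            exon_lengths=exon_lengths,
            utr5=utr5,
            cds_codons=cds_codons,
            events=(ev,),
            intron_length=int(rng.integers(60, 200)),
        )
    raise FixtureConstraintError("could not draw a valid random fixture spec")


# ---------------------------------------------------------------------------
# Simulations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    true_alt_fraction: Optional[float] = None  # per-event default when None
    n_reads: int = 10_000
    replicates: int = 5
    groups: tuple[str, ...] = ("IHC", "OHC")
    seed: int = DEFAULT_SEED
    segment_folds: Mapping[str, float] = field(
        default_factory=lambda: {"apical": 1.0, "middle": 2 ** 0.5, "basal": 2.0}
    )
    ct_noise_sd: float = 0.2
    ct_baseline_target: float = 25.0
    ct_baseline_reference: float = 20.0

    def __post_init__(self) -> None:
        if self.true_alt_fraction is not None and not (0 <= self.true_alt_fraction <= 1):
            raise ValueError("true_alt_fraction must be in [0, 1]")
        if self.n_reads <= 0 or self.replicates < 1:
            raise ValueError("n_reads must be > 0 and replicates >= 1")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")


def simulate_junction_counts(
    event: SpliceEvent,
    config: SimulationConfig,
    psi: Optional[float] = None,
    seed: Optional[int] = None,
) -> JunctionTable:
    """Binomial junction counts for one event.

    Per group and replicate the alternative-junction count is
    Binomial(n_reads, psi) and every constitutive junction carries the
    complementary count.  The generator is seeded and isolated per call.
    """
    if psi is None:
        psi = config.true_alt_fraction
    if psi is None:
        raise ValueError("no alternative fraction given (psi or config.true_alt_fraction)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records = []
    for group in config.groups:
        for rep in range(1, config.replicates + 1):
            n_alt = int(rng.binomial(config.n_reads, psi))
            n_const = config.n_reads - n_alt
            for j in event.alternative_junctions:
                records.append((j, group, str(rep), n_alt))
            for j in event.constitutive_junctions:
                records.append((j, group, str(rep), n_const))
    return JunctionTable.from_records(records)


def simulate_fixture_counts(fixture: Fixture, config: SimulationConfig) -> JunctionTable:
    """Counts for every event of a fixture at its default mixture."""
    tables = []
    for idx, event in enumerate(fixture.events):
        child = np.random.default_rng([config.seed, idx])
        seed = int(child.integers(2 ** 31))
        tables.append(
            simulate_junction_counts(
                event, config, psi=fixture.mixtures[event.event_id], seed=seed
            )
        )
    return JunctionTable.concat(tables)


def simulate_ct(
    config: SimulationConfig,
    targets: Optional[Mapping[str, Mapping[str, float]]] = None,
    reference_target: str = "GAPDH",
    seed: Optional[int] = None,
) -> list[CtRecord]:
    """CT values for a tonotopic-gradient experiment.

    CT(target) = baseline - log2(fold) + N(0, sd); the reference gene sits
    at a constant baseline plus noise.  One record per target and per
    reference, per segment and replicate.
    """
    if targets is None:
        targets = {"target_alt": dict(config.segment_folds)}
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[CtRecord] = []
    for segment in SEGMENTS:
        for rep in range(1, config.replicates + 1):
            sample = f"{segment}_r{rep}"
            noise_ref = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
            records.append(
                CtRecord(
                    sample_id=sample,
                    segment=segment,
                    target=reference_target,
                    reference_target=reference_target,
                    ct_value=config.ct_baseline_reference + noise_ref,
                    replicate=str(rep),
                )
            )
            for target, folds in targets.items():
                fold = folds.get(segment, 1.0)
                noise = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
                records.append(
                    CtRecord(
                        sample_id=sample,
                        segment=segment,
                        target=target,
                        reference_target=reference_target,
                        ct_value=config.ct_baseline_target - np.log2(fold) + noise,
                        replicate=str(rep),
                    )
                )
    return records


def write_fixture_dir(outdir, seed: int = DEFAULT_SEED,
                      config: Optional[SimulationConfig] = None) -> dict[str, Path]:
    """Generate all fixtures plus simulated inputs into a directory.

    Writes genome FASTA, gene-model GTF, per-replicate junction tables with
    a manifest, a CT table, and the true event list; returns the paths.
    """
    from . import io as _io
    from .qpcr import write_ct_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = SimulationConfig(seed=seed)
    elif config.seed != seed:
        config = replace(config, seed=seed)

    fixtures = [make_fixture(name, seed=seed) for name in FIXTURE_NAMES]
    genome: dict[str, str] = {}
    genes, all_events, tables = [], [], []
    for fx in fixtures:
        genome.update(fx.genome)
        genes.append(fx.gene_model)
        all_events.extend(fx.events)
        tables.append(simulate_fixture_counts(fx, config))

    paths = {
        "genome": outdir / "genome.fa",
        "gtf": outdir / "models.gtf",
        "events": outdir / "true_events.tsv",
        "ct": outdir / "ct.tsv",
    }
    _io.write_fasta(genome, paths["genome"])
    _io.write_gtf(genes, paths["gtf"])
    _io.write_events_tsv(all_events, paths["events"])
    paths["manifest"] = _io.write_junction_table(JunctionTable.concat(tables), outdir)
    ct_rng = np.random.default_rng([seed, 99])
    records = simulate_ct(
        config,
        targets={
            "Tmc1_alt": dict(config.segment_folds),
            "Tmc1_const": {s: 1.0 for s in SEGMENTS},
        },
        seed=int(ct_rng.integers(2 ** 31)),
    )
    write_ct_table(records, paths["ct"])
    return paths
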