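"""Alternative-splicing event detection and AS-ratio quantification.

An event is inferred by comparing observed junctions (intron intervals
with read support) against the introns of a gene's canonical transcript:

* ``exon_skipping`` — observed junction uses the donor of annotated intron
  *i* and the acceptor of intron *i+1*, excising exactly one exon;
* ``alt_3ss`` — shares a donor with an annotated intron but uses a
  different acceptor, moving the downstream exon's 5' boundary;
* ``alt_5ss`` — shares an acceptor, different donor within the annotated
  upstream exon or intron;
* ``alt_first_exon`` — shares an acceptor, donor 5' of the annotated
  upstream exon (alternative transcription start, as for the two TMC1
  N-termini); classified but excluded from AS-ratio reports by default
  since it is not a splicing choice between shared exons.

The AS ratio of an event in one cell-type group is the proportion of
reads on alternative junctions among reads on
alternative plus constitutive junctions, pooled across replicates.  When
an event carries more than one junction on a side (exon skipping has two
flanking constitutive junctions), the side's count is the rounded mean
across its junctions so the constitutive isoform is not double-counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .model import GeneModel, GenomicInterval, Junction, JunctionTable, ModelError

EVENT_TYPES = ("exon_skipping", "alt_3ss", "alt_5ss", "alt_first_exon")


@dataclass(frozen=True)
class SpliceEvent:
    """A typed alternative-splicing event with its junction evidence sets."""

    event_id: str
    gene_id: str
    event_type: str
    constitutive_junctions: tuple[Junction, ...]
    alternative_junctions: tuple[Junction, ...]
    affected_region: GenomicInterval

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ModelError(f"unknown event type {self.event_type!r}")
        ckeys = {j.key for j in self.constitutive_junctions}
        akeys = {j.key for j in self.alternative_junctions}
        if ckeys & akeys:
            raise ModelError("constitutive and alternative junction sets overlap")
        if self.event_type == "alt_3ss" and self.alternative_junctions:
            donors = {j.donor_pos for j in self.constitutive_junctions} | {
                j.donor_pos for j in self.alternative_junctions
            }
            if len(donors) != 1:
                raise ModelError("alt_3ss junctions must share the donor coordinate")
        if self.event_type == "alt_5ss" and self.alternative_junctions:
            acceptors = {j.acceptor_pos for j in self.constitutive_junctions} | {
                j.acceptor_pos for j in self.alternative_junctions
            }
            if len(acceptors) != 1:
                raise ModelError("alt_5ss junctions must share the acceptor coordinate")


@dataclass(frozen=True)
class ASRatioEstimate:
    """Pooled AS ratio for one event in one group, with a Wilson 95% CI."""

    event_id: str
    group: str
    n_alt: int
    n_const: int
    ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    per_replicate_ratios: tuple = ()
    undefined: bool = False


@dataclass(frozen=True)
class GroupComparison:
    event_id: str
    group_a: str
    group_b: str
    ratio_a: float
    ratio_b: float
    difference: float
    fisher_p: Optional[float] = None


@dataclass
class DetectionResult:
    events: list[SpliceEvent]
    unclassified: list[GenomicInterval] = field(default_factory=list)


def _classify(
    tx, obs: GenomicInterval
) -> Optional[tuple[str, tuple[GenomicInterval, ...], GenomicInterval]]:
    """Classify one observed junction against a transcript's annotated introns.

    Returns (event_type, constitutive introns, affected region) or None.
    """
    introns = tx.introns()
    if not introns:
        return None
    strand = tx.strand

    def donor(iv: GenomicInterval) -> int:
        return iv.start if strand == "+" else iv.end

    def acceptor(iv: GenomicInterval) -> int:
        return iv.end if strand == "+" else iv.start

    donor_idx = {donor(iv): i for i, iv in enumerate(introns)}
    acceptor_idx = {acceptor(iv): i for i, iv in enumerate(introns)}
    di = donor_idx.get(donor(obs))
    ai = acceptor_idx.get(acceptor(obs))

    if di is not None and ai is not None:
        if ai == di:  # annotated intron; caller filters these beforehand
            return None
        if ai == di + 1:
            skipped = tx.exons[di + 1]
            return "exon_skipping", (introns[di], introns[ai]), skipped
        return None  # multi-exon skip: out of scope, reported unclassified

    if di is not None:  # shared donor, novel acceptor -> alt 3'SS
        iv0 = introns[di]
        a0, a = acceptor(iv0), acceptor(obs)
        if strand == "+":
            region = GenomicInterval(obs.chrom, min(a0, a) + 1, max(a0, a), "+")
        else:
            region = GenomicInterval(obs.chrom, min(a0, a), max(a0, a) - 1, "-")
        return "alt_3ss", (iv0,), region

    if ai is not None:  # shared acceptor, novel donor
        iv0 = introns[ai]
        upstream_exon = tx.exons[ai]
        d0, d = donor(iv0), donor(obs)
        before_exon = (
            d < upstream_exon.start if strand == "+" else d > upstream_exon.end
        )
        if strand == "+":
            region = GenomicInterval(obs.chrom, min(d0, d), max(d0, d) - 1, "+")
        else:
            region = GenomicInterval(obs.chrom, min(d0, d) + 1, max(d0, d), "-")
        kind = "alt_first_exon" if before_exon else "alt_5ss"
        return kind, (iv0,), region

    return None


def _event_id(gene_id: str, kind: str, region: GenomicInterval) -> str:
    return f"{gene_id}:{kind}:{region.chrom}:{region.start}-{region.end}"


def detect_events(
    gene_model: GeneModel,
    junction_table: JunctionTable,
    min_replicates: Optional[int] = None,
    return_unclassified: bool = False,
):
    """Detect alternative-splicing events for one gene from junction evidence.

    ``min_replicates`` defaults to ceil(0.8 * R) over the R replicates in the
    table (the 4-of-5 reproducibility rule); an event is kept when its
    alternative junction has reads in at least that many replicates of some
    group.  Junctions matching no supported pattern are collected in a side
    list, returned when ``return_unclassified`` is set.
    """
    tx = gene_model.canonical_transcript
    if len(tx.exons) < 2:
        raise ModelError(
            f"gene {gene_model.gene_id}: canonical transcript has no introns"
        )
    if min_replicates is not None and min_replicates < 1:
        raise ValueError("min_replicates must be >= 1")

    result = DetectionResult(events=[])
    if len(junction_table) == 0:
        return (result.events, result.unclassified) if return_unclassified else result.events

    if min_replicates is None:
        min_replicates = math.ceil(0.8 * len(junction_table.replicates))

    span = tx.span
    sub = junction_table.subset(tx.chrom, tx.strand, span.start, span.end)
    annotated = {(iv.start, iv.end) for iv in tx.introns()}
    seen: set[str] = set()
    for obs in sub.junctions():
        if (obs.start, obs.end) in annotated:
            continue
        cls = _classify(tx, obs)
        if cls is None:
            result.unclassified.append(obs)
            continue
        kind, const_ivs, region = cls
        if sub.support_replicates(obs) < min_replicates:
            continue
        eid = _event_id(gene_model.gene_id, kind, region)
        if eid in seen:
            continue
        seen.add(eid)
        result.events.append(
            SpliceEvent(
                event_id=eid,
                gene_id=gene_model.gene_id,
                event_type=kind,
                constitutive_junctions=tuple(Junction(iv) for iv in const_ivs),
                alternative_junctions=(Junction(obs),),
                affected_region=region,
            )
        )
    result.events.sort(key=lambda ev: (ev.affected_region.start, ev.event_type))
    return (result.events, result.unclassified) if return_unclassified else result.events


def _side_count(table: JunctionTable, junctions, group, replicate=None) -> int:
    """Rounded mean pooled count across one side's junctions."""
    if not junctions:
        return 0
    vals = []
    for j in junctions:
        if replicate is None:
            vals.append(table.pooled_count(j.interval, group))
        else:
            vals.append(table.replicate_counts(j.interval, group).get(replicate, 0))
    return int(round(sum(vals) / len(vals)))


def as_ratio(event: SpliceEvent, junction_table: JunctionTable, group: str) -> ASRatioEstimate:
    """The AS-ratio statistic: n_alt / (n_alt + n_const), pooled across replicates.

    Reports a Wilson 95% CI on the pooled proportion and per-replicate
    ratios; a zero total is flagged undefined rather than raising.
    """
    if group not in junction_table.groups:
        raise ValueError(f"group {group!r} not present in junction table")
    n_alt = _side_count(junction_table, event.alternative_junctions, group)
    n_const = _side_count(junction_table, event.constitutive_junctions, group)
    total = n_alt + n_const
    per_rep = []
    for rep in junction_table.replicates:
        a = _side_count(junction_table, event.alternative_junctions, group, rep)
        c = _side_count(junction_table, event.constitutive_junctions, group, rep)
        per_rep.append(a / (a + c) if a + c > 0 else None)
    if total == 0:
        return ASRatioEstimate(
            event.event_id, group, 0, 0, None, None, None, tuple(per_rep), undefined=True
        )
    lo, hi = proportion_confint(n_alt, total, alpha=0.05, method="wilson")
    return ASRatioEstimate(
        event_id=event.event_id,
        group=group,
        n_alt=n_alt,
        n_const=n_const,
        ratio=n_alt / total,
        ci_low=float(lo),
        ci_high=float(hi),
        per_replicate_ratios=tuple(per_rep),
    )


def compare_groups(
    event: SpliceEvent,
    junction_table: JunctionTable,
    group_a: str,
    group_b: str,
    fisher: bool = True,
) -> GroupComparison:
    """Difference of pooled AS ratios between two groups (e.g. OHC vs IHC).

    A two-sided Fisher exact test on the pooled 2x2 count table is
    reported for reference; the comparison itself is descriptive.
    """
    est_a = as_ratio(event, junction_table, group_a)
    est_b = as_ratio(event, junction_table, group_b)
    if est_a.undefined or est_b.undefined:
        raise ValueError("cannot compare groups with zero total counts")
    p = None
    if fisher:
        _, p = stats.fisher_exact(
            [[est_a.n_alt, est_a.n_const], [est_b.n_alt, est_b.n_const]],
            alternative="two-sided",
        )
        p = float(p)
    return GroupComparison(
        event_id=event.event_id,
        group_a=group_a,
        group_b=group_b,
        ratio_a=est_a.ratio,
        ratio_b=est_b.ratio,
        difference=est_a.ratio - est_b.ratio,
        fisher_p=p,
    )
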