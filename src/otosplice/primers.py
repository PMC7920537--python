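"""Event-flanking and isoform-discriminating primer design.

Two strategies mirror standard isoform validation practice:

* flanking pairs — forward primer in the exon upstream of the event,
  reverse primer downstream, so the two isoforms give PCR products whose
  length difference equals the event's removed segment;
* discriminating primers — a reverse primer whose 3' end crosses the
  target isoform's splice junction by ``k`` nucleotides (default 2).  The
  primer matches the target isoform perfectly while its 3'-terminal bases
  mismatch the other isoform, suppressing its amplification: mismatches in
  the last few bases of a primer's 3' end reduce priming far more than
  distal ones, the principle behind allele-specific PCR.

Mismatch reports count against the best (minimum-mismatch) ungapped
placement of the primer on each isoform template; the weighted penalty
uses a step function, ``terminal_weight`` within the 3'-terminal window
and ``distal_weight`` outside it.

Melting temperatures are nearest-neighbor estimates at 50 mM monovalent
salt and 500 nM primer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .consequence import apply_event
from .events import SpliceEvent
from .model import GeneModel, TranscriptModel, reverse_complement


class PrimerDesignError(ValueError):
    """No primer satisfying the constraints could be placed."""


@dataclass(frozen=True)
class PrimerParams:
    min_length: int = 18
    max_length: int = 25
    tm_min: float = 57.0
    tm_max: float = 63.0
    overhang: int = 2            # nt by which a discriminating primer crosses the site
    terminal_window: int = 5     # 3' positions with elevated mismatch weight
    terminal_weight: float = 4.0
    distal_weight: float = 1.0
    salt_mM: float = 50.0
    primer_nM: float = 500.0

    def __post_init__(self) -> None:
        if self.overhang < 0:
            raise ValueError("overhang must be >= 0")
        if self.terminal_window < 1:
            raise ValueError("terminal_window must be >= 1")
        if self.min_length < 8 or self.max_length < self.min_length:
            raise ValueError("bad primer length range")


@dataclass(frozen=True)
class PrimerCandidate:
    sequence: str                 # 5'->3'
    orientation: str              # forward | reverse
    template_start: int           # 1-based position on the spliced template
    template_end: int
    tm: float

    def __post_init__(self) -> None:
        if set(self.sequence.upper()) - set("ACGT"):
            raise ValueError("primer sequence must be over {A,C,G,T}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be forward or reverse")


@dataclass(frozen=True)
class DiscriminationReport:
    target_isoform: str
    mismatches_vs_constitutive: int
    mismatches_vs_alternative: int
    positions_vs_constitutive: tuple[int, ...]  # distances from the 3' end, 1 = terminal
    positions_vs_alternative: tuple[int, ...]
    penalty_vs_constitutive: float
    penalty_vs_alternative: float
    discriminating: bool


@dataclass(frozen=True)
class FlankingPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    amplicon_constitutive_nt: int
    amplicon_alternative_nt: int


def melting_temperature(
    sequence: str, salt_mM: float = 50.0, primer_nM: float = 500.0
) -> float:
    """Nearest-neighbor Tm (unified parameter set) in deg C."""
    sequence = sequence.upper()
    if len(sequence) < 8:
        raise ValueError("Tm estimate requires at least 8 nt")
    if set(sequence) - set("ACGT"):
        raise ValueError("sequence must be over {A,C,G,T}")
    return float(
        _mt.Tm_NN(sequence, Na=salt_mM, dnac1=primer_nM, dnac2=0, selfcomp=False)
    )


def mismatch_penalty(
    distances: Sequence[int], params: PrimerParams = PrimerParams()
) -> float:
    """Position-weighted mismatch penalty.

    Each mismatch at 3'-end distance d contributes ``terminal_weight`` when
    d <= terminal_window and ``distal_weight`` otherwise — a step-function
    encoding of the rule that 3'-terminal mismatches disrupt priming most.
    """
    total = 0.0
    for d in distances:
        if d < 1:
            raise ValueError("3' distance must be >= 1")
        total += params.terminal_weight if d <= params.terminal_window else params.distal_weight
    return total


def _best_placement(window: str, template: str) -> tuple[int, tuple[int, ...]]:
    """Minimum-mismatch ungapped placement of a template-sense window.

    Returns (mismatch count, distances of mismatches from the primer 3' end)
    at the best offset; ties break toward the leftmost offset.  Window
    position 0 pairs with the primer's 3'-terminal base.
    """
    L = len(window)
    if L > len(template):
        return L, tuple(range(1, L + 1))
    best_n, best_pos = L + 1, ()
    for off in range(len(template) - L + 1):
        seg = template[off : off + L]
        pos = tuple(i + 1 for i in range(L) if window[i] != seg[i])
        if len(pos) < best_n:
            best_n, best_pos = len(pos), pos
            if best_n == 0:
                break
    return best_n, best_pos


def score_window(
    window: str,
    constitutive_template: str,
    alternative_template: str,
    target_isoform: str,
    params: PrimerParams = PrimerParams(),
) -> DiscriminationReport:
    """Score a template-sense primer window against both isoform templates."""
    n_c, pos_c = _best_placement(window.upper(), constitutive_template.upper())
    n_a, pos_a = _best_placement(window.upper(), alternative_template.upper())
    if target_isoform == "alternative":
        n_target, n_other, pos_other = n_a, n_c, pos_c
    elif target_isoform == "constitutive":
        n_target, n_other, pos_other = n_c, n_a, pos_a
    else:
        raise ValueError("target_isoform must be 'constitutive' or 'alternative'")
    discriminating = n_target == 0 and any(
        d <= params.terminal_window for d in pos_other
    )
    return DiscriminationReport(
        target_isoform=target_isoform,
        mismatches_vs_constitutive=n_c,
        mismatches_vs_alternative=n_a,
        positions_vs_constitutive=pos_c,
        positions_vs_alternative=pos_a,
        penalty_vs_constitutive=mismatch_penalty(pos_c, params),
        penalty_vs_alternative=mismatch_penalty(pos_a, params),
        discriminating=discriminating,
    )


def score_primer(
    primer_sequence: str,
    orientation: str,
    constitutive_template: str,
    alternative_template: str,
    target_isoform: str,
    params: PrimerParams = PrimerParams(),
) -> DiscriminationReport:
    """Re-score a user-supplied primer (5'->3') against both isoform mRNAs."""
    seq = primer_sequence.upper()
    if orientation == "reverse":
        # template-sense window, 5'->3'; its first base pairs the primer 3' end
        window = reverse_complement(seq)
    elif orientation == "forward":
        window = seq
        # for a forward primer the 3' end is the window's *last* base; flip so
        # index 0 pairs with the 3' end, matching _best_placement's convention
        return _score_forward(window, constitutive_template, alternative_template,
                              target_isoform, params)
    else:
        raise ValueError("orientation must be forward or reverse")
    return score_window(
        window, constitutive_template, alternative_template, target_isoform, params
    )


def _score_forward(window, const_t, alt_t, target, params):
    def placement(template):
        L = len(window)
        best_n, best_pos = L + 1, tuple(range(1, L + 1))
        for off in range(max(0, len(template) - L + 1)):
            seg = template[off : off + L]
            pos = tuple(L - i for i in range(L) if window[i] != seg[i])
            if len(pos) < best_n:
                best_n, best_pos = len(pos), tuple(sorted(pos))
                if best_n == 0:
                    break
        return best_n, best_pos

    n_c, pos_c = placement(const_t.upper())
    n_a, pos_a = placement(alt_t.upper())
    n_target = n_a if target == "alternative" else n_c
    pos_other = pos_c if target == "alternative" else pos_a
    return DiscriminationReport(
        target_isoform=target,
        mismatches_vs_constitutive=n_c,
        mismatches_vs_alternative=n_a,
        positions_vs_constitutive=pos_c,
        positions_vs_alternative=pos_a,
        penalty_vs_constitutive=mismatch_penalty(pos_c, params),
        penalty_vs_alternative=mismatch_penalty(pos_a, params),
        discriminating=n_target == 0
        and any(d <= params.terminal_window for d in pos_other),
    )


# ---------------------------------------------------------------------------
# Design against a gene model
# ---------------------------------------------------------------------------

def _isoform_templates(
    gene_model: GeneModel, event: SpliceEvent, genome: Mapping[str, str]
) -> tuple[TranscriptModel, TranscriptModel, str, str]:
    tx = gene_model.canonical_transcript
    alt_tx = apply_event(tx, event)
    return tx, alt_tx, tx.spliced_sequence(genome), alt_tx.spliced_sequence(genome)


def _tm_candidates(region: str, params: PrimerParams):
    """All (start0, length, Tm) windows within a region string."""
    for L in range(params.min_length, params.max_length + 1):
        for s in range(0, len(region) - L + 1):
            yield s, L, melting_temperature(
                region[s : s + L], params.salt_mM, params.primer_nM
            )


def _pick(cands, prefer_late: bool, params: PrimerParams):
    """Prefer Tm-in-range windows closest to the event; else fail."""
    in_range = [c for c in cands if params.tm_min <= c[2] <= params.tm_max]
    if not in_range:
        return None
    mid = (params.tm_min + params.tm_max) / 2
    if prefer_late:
        return max(in_range, key=lambda c: (c[0] + c[1], -abs(c[2] - mid)))
    return min(in_range, key=lambda c: (c[0], abs(c[2] - mid)))


def design_flanking_pair(
    gene_model: GeneModel,
    event: SpliceEvent,
    params: PrimerParams = PrimerParams(),
    genome: Optional[Mapping[str, str]] = None,
) -> FlankingPair:
    """Design a forward/reverse pair in the exons flanking the event.

    Predicted amplicon lengths are reported for both isoforms; their
    difference equals the event's removed-segment length.
    """
    if genome is None:
        raise PrimerDesignError("a genome sequence is required for primer design")
    tx, alt_tx, const_mrna, _ = _isoform_templates(gene_model, event, genome)

    region = event.affected_region
    r5 = region.start if tx.strand == "+" else region.end
    r3 = region.end if tx.strand == "+" else region.start
    sp5 = tx.genomic_to_spliced(r5)  # first affected spliced base
    sp3 = tx.genomic_to_spliced(r3)

    # upstream exon: the exon ending immediately before the affected region
    exon_bounds = []
    acc = 0
    for e in tx.exons:
        exon_bounds.append((acc + 1, acc + e.length))
        acc += e.length
    up = [i for i, (s, t) in enumerate(exon_bounds) if t < sp5]
    if not up:
        raise PrimerDesignError("event has no upstream exon to place a forward primer")
    ui = up[-1]
    # restrict to the immediately flanking exon, as in exon-8/exon-10 designs
    us, ut = exon_bounds[ui]
    fwd_region = const_mrna[us - 1 : ut]
    fc = _pick(_tm_candidates(fwd_region, params), prefer_late=True, params=params)
    if fc is None:
        raise PrimerDesignError(
            f"no forward primer with Tm in [{params.tm_min}, {params.tm_max}] in "
            f"the upstream exon (length {len(fwd_region)})"
        )
    fs0, fL, ftm = fc
    fwd = PrimerCandidate(
        sequence=fwd_region[fs0 : fs0 + fL],
        orientation="forward",
        template_start=us + fs0,
        template_end=us + fs0 + fL - 1,
        tm=ftm,
    )

    # downstream region: sequence 3' of the affected region, within the exon
    # that follows it (after the alternative acceptor for alt 3'SS events)
    down = [i for i, (s, t) in enumerate(exon_bounds) if s > sp3]
    if event.event_type == "alt_3ss":
        # affected region sits at the head of an exon; use that exon's remainder
        holder = [i for i, (s, t) in enumerate(exon_bounds) if s <= sp3 <= t and t > sp3]
        rs = sp3 + 1
        rt = exon_bounds[holder[0]][1] if holder else None
        if rt is None:
            if not down:
                raise PrimerDesignError("event has no downstream exon for a reverse primer")
            rs, rt = exon_bounds[down[0]]
    else:
        if not down:
            raise PrimerDesignError("event has no downstream exon for a reverse primer")
        rs, rt = exon_bounds[down[0]]
    rev_region = const_mrna[rs - 1 : rt]
    rc = _pick(_tm_candidates(rev_region, params), prefer_late=False, params=params)
    if rc is None:
        raise PrimerDesignError(
            f"no reverse primer with Tm in [{params.tm_min}, {params.tm_max}] in "
            f"the downstream exon (length {len(rev_region)})"
        )
    rs0, rL, rtm = rc
    rev = PrimerCandidate(
        sequence=reverse_complement(rev_region[rs0 : rs0 + rL]),
        orientation="reverse",
        template_start=rs + rs0,
        template_end=rs + rs0 + rL - 1,
        tm=rtm,
    )

    amp_const = rev.template_end - fwd.template_start + 1
    removed = sp3 - sp5 + 1  # affected bases lie between the primers
    return FlankingPair(
        forward=fwd,
        reverse=rev,
        amplicon_constitutive_nt=amp_const,
        amplicon_alternative_nt=amp_const - removed,
    )


def design_discriminating_primer(
    gene_model: GeneModel,
    event: SpliceEvent,
    target_isoform: str,
    params: PrimerParams = PrimerParams(),
    genome: Optional[Mapping[str, str]] = None,
) -> tuple[PrimerCandidate, DiscriminationReport]:
    """Design a junction-crossing reverse primer specific to one isoform.

    The primer's 3' end crosses the target isoform's splice boundary by
    ``params.overhang`` nucleotides, so its terminal bases pair with the
    sequence that distinguishes the target isoform from the other.
    """
    if genome is None:
        raise PrimerDesignError("a genome sequence is required for primer design")
    tx, alt_tx, const_mrna, alt_mrna = _isoform_templates(gene_model, event, genome)

    region = event.affected_region
    r5 = region.start if tx.strand == "+" else region.end
    r3 = region.end if tx.strand == "+" else region.start
    if target_isoform == "alternative":
        template = alt_mrna
        # first retained base after the alternative junction, in alt coordinates
        aj = event.alternative_junctions[0].interval
        nxt = aj.end + 1 if tx.strand == "+" else aj.start - 1
        jpos = alt_tx.genomic_to_spliced(nxt) - 1
    elif target_isoform == "constitutive":
        template = const_mrna
        jpos = tx.genomic_to_spliced(r5) - 1  # first base absent from the alt isoform
    else:
        raise PrimerDesignError("target_isoform must be 'constitutive' or 'alternative'")

    k = params.overhang
    win_start = jpos - k
    if win_start < 0:
        raise PrimerDesignError("junction context shorter than the requested overhang")
    avail = len(template) - win_start
    if avail < params.min_length:
        raise PrimerDesignError(
            f"junction context of {avail} nt is shorter than the minimum primer "
            f"length {params.min_length}"
        )
    best = None
    mid = (params.tm_min + params.tm_max) / 2
    for L in range(params.min_length, min(params.max_length, avail) + 1):
        window = template[win_start : win_start + L]
        tm = melting_temperature(window, params.salt_mM, params.primer_nM)
        key = (not (params.tm_min <= tm <= params.tm_max), abs(tm - mid))
        if best is None or key < best[0]:
            best = (key, window, tm)
    _, window, tm = best
    primer = PrimerCandidate(
        sequence=reverse_complement(window),
        orientation="reverse",
        template_start=win_start + 1,
        template_end=win_start + len(window),
        tm=tm,
    )
    report = score_window(window, const_mrna, alt_mrna, target_isoform, params)
    return primer, report
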