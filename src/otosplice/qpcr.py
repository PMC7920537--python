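"""Relative qPCR quantification (delta-delta-CT) and tonotopic gradient tests.

Relative expression of a target against a reference gene (e.g. GAPDH) is
2^-(ddCT) with dCT = CT(target) - CT(reference) matched within a sample,
and ddCT = dCT - mean dCT of the calibrator segment (default apical).
Amplification efficiency is fixed at 2 per cycle, the classical ddCT
assumption.

Gradients along the cochlear apex-to-base axis are assessed with unpaired
two-sided Student's t tests per segment pair (equal-variance by default,
Welch by flag), with no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SEGMENTS = ("apical", "middle", "basal")


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    segment: str
    target: str
    reference_target: str
    ct_value: float
    replicate: str

    def __post_init__(self) -> None:
        if not (0.0 < self.ct_value < 45.0):
            raise ValueError(f"CT value {self.ct_value} outside (0, 45)")


@dataclass(frozen=True)
class RelExpression:
    sample_id: str
    segment: str
    target: str
    replicate: str
    delta_ct: float
    delta_delta_ct: float
    rel_expr: float


@dataclass(frozen=True)
class SegmentStats:
    segment: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class PairTest:
    segment_a: str
    segment_b: str
    t_statistic: Optional[float]
    p_value: Optional[float]
    significant: Optional[bool]
    untestable: bool = False


@dataclass(frozen=True)
class GradientReport:
    target: str
    segments: tuple[SegmentStats, ...]
    pairs: tuple[PairTest, ...]


def read_ct_table(path) -> list[CtRecord]:
    """CT input TSV with columns sample, segment, target, reference, ct, replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "replicate": str})
    need = {"sample", "segment", "target", "reference", "ct", "replicate"}
    if not need <= set(df.columns):
        raise ValueError(f"CT table must have columns {sorted(need)}")
    return [
        CtRecord(
            sample_id=r.sample,
            segment=r.segment,
            target=r.target,
            reference_target=r.reference,
            ct_value=float(r.ct),
            replicate=str(r.replicate),
        )
        for r in df.itertuples()
    ]


def write_ct_table(records: Sequence[CtRecord], path) -> None:
    pd.DataFrame(
        [
            dict(
                sample=r.sample_id,
                segment=r.segment,
                target=r.target,
                reference=r.reference_target,
                ct=r.ct_value,
                replicate=r.replicate,
            )
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def delta_delta_ct(
    records: Sequence[CtRecord],
    reference_target: Optional[str] = None,
    calibrator_segment: str = "apical",
) -> list[RelExpression]:
    """Relative expression 2^-(ddCT) for every non-reference record.

    Every (sample, segment, replicate, target) needs a matching reference
    record; a missing one raises an error naming the sample.  The
    calibrator dCT is the mean dCT of the calibrator segment per target.
    """
    if not records:
        return []
    if reference_target is None:
        refs = {r.reference_target for r in records}
        if len(refs) != 1:
            raise ValueError(f"ambiguous reference target: {sorted(refs)}")
        reference_target = refs.pop()

    ref_ct: dict[tuple, float] = {}
    for r in records:
        if r.target == reference_target:
            ref_ct[(r.sample_id, r.segment, r.replicate)] = r.ct_value

    targets = [r for r in records if r.target != reference_target]
    dct: list[tuple[CtRecord, float]] = []
    for r in targets:
        key = (r.sample_id, r.segment, r.replicate)
        if key not in ref_ct:
            raise ValueError(
                f"no {reference_target} reference record for sample "
                f"{r.sample_id!r} (segment {r.segment}, replicate {r.replicate})"
            )
        dct.append((r, r.ct_value - ref_ct[key]))

    calib: dict[str, float] = {}
    for target in {r.target for r in targets}:
        vals = [d for r, d in dct if r.target == target and r.segment == calibrator_segment]
        if not vals:
            raise ValueError(
                f"no records in calibrator segment {calibrator_segment!r} for "
                f"target {target!r}"
            )
        calib[target] = float(np.mean(vals))

    out = []
    for r, d in dct:
        ddct = d - calib[r.target]
        out.append(
            RelExpression(
                sample_id=r.sample_id,
                segment=r.segment,
                target=r.target,
                replicate=r.replicate,
                delta_ct=d,
                delta_delta_ct=ddct,
                rel_expr=float(2.0 ** (-ddct)),
            )
        )
    return out


def gradient_test(
    rel_expressions: Sequence[RelExpression],
    target: str,
    segments: Sequence[str] = SEGMENTS,
    alpha: float = 0.05,
    welch: bool = False,
) -> GradientReport:
    """Segment means +/- SEM and pairwise Student's t tests for one target.

    Pairs where either segment has fewer than two replicates are flagged
    untestable rather than raising.
    """
    vals = {
        seg: np.array(
            [e.rel_expr for e in rel_expressions if e.target == target and e.segment == seg]
        )
        for seg in segments
    }
    seg_stats = tuple(
        SegmentStats(
            segment=seg,
            n=len(v),
            mean=float(np.mean(v)) if len(v) else float("nan"),
            sem=float(stats.sem(v)) if len(v) >= 2 else float("nan"),
        )
        for seg, v in vals.items()
    )
    pairs = []
    for a, b in combinations(segments, 2):
        va, vb = vals[a], vals[b]
        if len(va) < 2 or len(vb) < 2:
            pairs.append(PairTest(a, b, None, None, None, untestable=True))
            continue
        t, p = stats.ttest_ind(va, vb, equal_var=not welch)
        pairs.append(
            PairTest(a, b, float(t), float(p), bool(p < alpha))
        )
    return GradientReport(target=target, segments=seg_stats, pairs=tuple(pairs))
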