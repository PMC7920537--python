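"""Event detection, the AS-ratio statistic, and group comparisons."""

import math

import numpy as np
import pytest

from otosplice.events import (
    SpliceEvent,
    as_ratio,
    compare_groups,
    detect_events,
)
from otosplice.model import (
    GenomicInterval,
    Junction,
    JunctionTable,
    ModelError,
    TranscriptModel,
)
from otosplice.model import GeneModel
from otosplice.simulate import SimulationConfig, simulate_junction_counts

# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _toy_gene(n_exons=6, exon_len=100, intron_len=100, strand="+"):
    exons = []
    pos = 1
    for _ in range(n_exons):
        exons.append(GenomicInterval("chrZ", pos, pos + exon_len - 1, strand))
        pos += exon_len + intron_len
    if strand == "-":
        exons = exons[::-1]
    tx = TranscriptModel("TZ", "GZ", tuple(exons))
    return GeneModel("GZ", (tx,), "TZ")


def _two_group_event():
    """A minimal alt 3'SS event plus a table builder for contrived counts."""
    const = Junction(GenomicInterval("c", 101, 200, "+"))
    alt = Junction(GenomicInterval("c", 101, 209, "+"))
    event = SpliceEvent(
        event_id="E",
        gene_id="G",
        event_type="alt_3ss",
        constitutive_junctions=(const,),
        alternative_junctions=(alt,),
        affected_region=GenomicInterval("c", 201, 209, "+"),
    )

    def table(counts):  # {(group, rep): (n_alt, n_const)}
        recs = []
        for (g, r), (na, nc) in counts.items():
            recs.append((alt, g, r, na))
            recs.append((const, g, r, nc))
        return JunctionTable.from_records(recs)

    return event, table


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def test_fixture_detection_types_and_regions(fixtures, sim_tables):
    by_gene = {}
    for name, fx in fixtures.items():
        by_gene[name] = detect_events(fx.gene_model, sim_tables[name])
    assert [e.event_type for e in by_gene["tmc1_like"]] == [
        "exon_skipping",
        "alt_3ss",
    ]
    assert by_gene["tmc1_like"][0].affected_region.length == 99
    assert by_gene["tmc1_like"][1].affected_region.length == 9
    assert [e.event_type for e in by_gene["lhfpl5_like"]] == ["alt_3ss"]
    assert by_gene["lhfpl5_like"][0].affected_region.length == 153
    assert [e.event_type for e in by_gene["tmie_like"]] == ["alt_3ss"]
    assert by_gene["tmie_like"][0].affected_region.length == 8


def test_empty_table_yields_no_events(tmc1):
    import pandas as pd

    empty = JunctionTable(pd.DataFrame(columns=list(JunctionTable.COLUMNS)))
    assert detect_events(tmc1.gene_model, empty) == []


def test_intronless_gene_is_an_error():
    tx = TranscriptModel("T", "G", (GenomicInterval("c", 1, 100, "+"),))
    gene = GeneModel("G", (tx,), "T")
    import pandas as pd

    empty = JunctionTable(pd.DataFrame(columns=list(JunctionTable.COLUMNS)))
    with pytest.raises(ModelError, match="introns"):
        detect_events(gene, empty)


def test_detection_invariant_to_row_order_and_replicate_relabeling(
    tmc1, sim_tables
):
    table = sim_tables["tmc1_like"]
    base = detect_events(tmc1.gene_model, table)
    shuffled = JunctionTable(
        table.df.sample(frac=1, random_state=1).reset_index(drop=True)
    )
    relabeled = table.df.copy()
    relabeled["replicate"] = relabeled["replicate"].map(
        {"1": "e", "2": "d", "3": "c", "4": "b", "5": "a"}
    )
    for other in (shuffled, JunctionTable(relabeled)):
        got = detect_events(tmc1.gene_model, other)
        assert [e.event_id for e in got] == [e.event_id for e in base]


def test_strict_replicate_threshold_returns_subset(tmc1, sim_tables):
    table = sim_tables["tmc1_like"]
    loose = {e.event_id for e in detect_events(tmc1.gene_model, table, min_replicates=1)}
    strict = {
        e.event_id
        for e in detect_events(
            tmc1.gene_model, table, min_replicates=len(table.replicates)
        )
    }
    assert strict <= loose


def test_replicate_support_rule_drops_unreproduced_junctions():
    gene = _toy_gene()
    tx = gene.canonical_transcript
    introns = tx.introns()
    skip = GenomicInterval("chrZ", introns[0].start, introns[1].end, "+")
    recs = []
    for rep in "12345":
        for iv in introns[:2]:
            recs.append((Junction(iv), "G", rep, 100))
        # alternative junction seen in only two of five replicates
        recs.append((Junction(skip), "G", rep, 10 if rep in "12" else 0))
    table = JunctionTable.from_records(recs)
    assert detect_events(gene, table) == []  # default threshold ceil(0.8*5)=4
    assert len(detect_events(gene, table, min_replicates=2)) == 1


def _oracle_classify(tx, obs):
    """Independent brute-force classification of one junction."""
    introns = tx.introns()
    strand = tx.strand
    donor = (lambda iv: iv.start) if strand == "+" else (lambda iv: iv.end)
    acceptor = (lambda iv: iv.end) if strand == "+" else (lambda iv: iv.start)
    for i, ii in enumerate(introns):
        if (obs.start, obs.end) == (ii.start, ii.end):
            return None
    donor_hits = [i for i, iv in enumerate(introns) if donor(obs) == donor(iv)]
    acceptor_hits = [i for i, iv in enumerate(introns) if acceptor(obs) == acceptor(iv)]
    if donor_hits and acceptor_hits:
        i, j = donor_hits[0], acceptor_hits[0]
        if j == i + 1:
            return ("exon_skipping", tx.exons[i + 1])
        return None  # multi-exon skip: unsupported, stays unclassified
    for i, ii in enumerate(introns):
        if donor(obs) == donor(ii) and not acceptor_hits:
            return ("alt_3ss", None)
    for i, ii in enumerate(introns):
        if acceptor(obs) == acceptor(ii) and not donor_hits:
            up = tx.exons[i]
            d = donor(obs)
            outside = d < up.start if strand == "+" else d > up.end
            return ("alt_first_exon" if outside else "alt_5ss", None)
    return None


@pytest.mark.parametrize("strand", ["+", "-"])
def test_detection_matches_brute_force_classifier(strand):
    """Randomized junction sets classify identically under both routes."""
    rng = np.random.default_rng(42)
    gene = _toy_gene(strand=strand)
    tx = gene.canonical_transcript
    introns = tx.introns()
    candidates = []
    for ii in introns:
        for jj in introns:
            if ii.start < jj.start:
                candidates.append(GenomicInterval("chrZ", ii.start, jj.end, strand))
    for ii in introns:
        for off in (-7, 5, 9):
            candidates.append(
                GenomicInterval("chrZ", ii.start, ii.end + off, strand)
            )
            candidates.append(
                GenomicInterval("chrZ", ii.start + off, ii.end, strand)
            )
    chosen = [candidates[i] for i in rng.choice(len(candidates), 20, replace=False)]
    recs = [(Junction(iv), "G", "1", 50) for iv in introns]
    recs += [(Junction(iv), "G", "1", int(rng.integers(1, 30))) for iv in chosen]
    table = JunctionTable.from_records(recs)
    got = detect_events(gene, table, min_replicates=1)
    got_map = {j.key: e.event_type for e in got for j in e.alternative_junctions}
    for iv in chosen:
        expect = _oracle_classify(tx, iv)
        key = (iv.chrom, iv.start, iv.end, iv.strand)
        if expect is None:
            assert key not in got_map
        else:
            assert got_map[key] == expect[0]
            if expect[0] == "exon_skipping":
                ev = next(e for e in got if e.alternative_junctions[0].key == key)
                assert ev.affected_region == expect[1]


# ---------------------------------------------------------------------------
# AS ratio
# ---------------------------------------------------------------------------


def test_as_ratio_printed_example_93_to_7():
    event, make = _two_group_event()
    table = make({("IHC", "1"): (7, 93)})
    est = as_ratio(event, table, "IHC")
    assert est.ratio == pytest.approx(0.07)
    assert (est.n_alt, est.n_const) == (7, 93)


def test_as_ratio_zero_alternative():
    event, make = _two_group_event()
    est = as_ratio(event, make({("G", "1"): (0, 50)}), "G")
    assert est.ratio == 0.0 and est.ci_low == 0.0


def test_as_ratio_zero_total_flagged_not_raised():
    event, make = _two_group_event()
    est = as_ratio(event, make({("G", "1"): (0, 0)}), "G")
    assert est.undefined and est.ratio is None


def test_as_ratio_wilson_ci_against_direct_formula():
    """Wilson score interval recomputed from its closed form."""
    event, make = _two_group_event()
    est = as_ratio(event, make({("G", "1"): (7, 93)}), "G")
    n, p, z = 100, 0.07, 1.959963984540054
    centre = (p + z * z / (2 * n)) / (1 + z * z / n)
    half = (z / (1 + z * z / n)) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    assert est.ci_low == pytest.approx(centre - half, abs=1e-12)
    assert est.ci_high == pytest.approx(centre + half, abs=1e-12)
    assert est.ci_low <= est.ratio <= est.ci_high


def test_as_ratio_complement_sums_to_one():
    event, make = _two_group_event()
    for na, nc in [(7, 93), (10, 90), (1, 1)]:
        a = as_ratio(event, make({("G", "1"): (na, nc)}), "G").ratio
        b = as_ratio(event, make({("G", "1"): (nc, na)}), "G").ratio
        assert a + b == pytest.approx(1.0)


def test_as_ratio_per_replicate_and_missing_group():
    event, make = _two_group_event()
    table = make({("G", "1"): (10, 90), ("G", "2"): (20, 80)})
    est = as_ratio(event, table, "G")
    assert est.per_replicate_ratios == (0.1, 0.2)
    assert est.ratio == pytest.approx(0.15)
    with pytest.raises(ValueError, match="group"):
        as_ratio(event, table, "nope")


def test_exon_skipping_constitutive_side_averages_flanking_junctions(
    tmc1, sim_tables
):
    """Both flanking junctions carry the constitutive count once, not twice."""
    skip = next(e for e in tmc1.events if e.event_type == "exon_skipping")
    table = sim_tables["tmc1_like"]
    est = as_ratio(skip, table, "IHC")
    single = table.pooled_count(skip.constitutive_junctions[0].interval, "IHC")
    assert est.n_const == pytest.approx(single, rel=0.01)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def test_compare_groups_difference():
    event, make = _two_group_event()
    table = make({("OHC", "1"): (10, 90), ("IHC", "1"): (4, 96)})
    cmp = compare_groups(event, table, "OHC", "IHC")
    assert cmp.difference == pytest.approx(0.06)


def test_compare_groups_identical_counts():
    event, make = _two_group_event()
    table = make({("A", "1"): (10, 90), ("B", "1"): (10, 90)})
    cmp = compare_groups(event, table, "A", "B")
    assert cmp.difference == 0.0
    assert cmp.fisher_p == pytest.approx(1.0)


def test_fisher_p_matches_hypergeometric_tail_enumeration():
    """Two-sided Fisher p recomputed by summing hypergeometric point masses."""
    event, make = _two_group_event()
    table = make({("A", "1"): (10, 90), ("B", "1"): (4, 96)})
    cmp = compare_groups(event, table, "A", "B")

    def point_mass(k, row1, row2, col1, n):
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    row1, row2, col1, n = 100, 100, 14, 200
    p_obs = point_mass(10, row1, row2, col1, n)
    total = sum(
        point_mass(k, row1, row2, col1, n)
        for k in range(max(0, col1 - row2), min(row1, col1) + 1)
        if point_mass(k, row1, row2, col1, n) <= p_obs * (1 + 1e-9)
    )
    assert cmp.fisher_p == pytest.approx(total, rel=1e-9)


def test_compare_groups_missing_group_errors():
    event, make = _two_group_event()
    with pytest.raises(ValueError):
        compare_groups(event, make({("A", "1"): (1, 9)}), "A", "B")


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("psi", [0.05, 0.07, 0.5])
def test_ratio_recovers_generating_mixture(psi):
    """|ratio - psi| < 3 sd in >= 99% of 500 single-replicate simulations."""
    event, _ = _two_group_event()
    n = 10_000
    bound = 3 * math.sqrt(psi * (1 - psi) / n)
    hits = 0
    for i in range(500):
        cfg = SimulationConfig(n_reads=n, replicates=1, groups=("G",))
        table = simulate_junction_counts(event, cfg, psi=psi, seed=int(1e6 + i))
        est = as_ratio(event, table, "G")
        hits += abs(est.ratio - psi) < bound
    assert hits >= 495
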