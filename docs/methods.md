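# Methods

## Coordinate and strand conventions

All coordinates are 1-based and inclusive (GTF convention) throughout;
0-based half-open inputs (BED-style intron tables) are converted at the
parser boundary.  A splice junction is stored as its intron interval:
`start` is the first intronic base, `end` the last.  The donor site is the
intron end adjacent to the upstream exon in transcript orientation — on
the minus strand this is the higher genomic coordinate — and all reported
dinucleotides and context windows are written in transcript orientation.
The CDS is stored as the genomic positions of the first base of the start
codon and the last base of the stop codon.

Group and replicate labels for junction files are taken from an explicit
manifest TSV (`file, group, replicate`), never guessed from filenames.

## Event detection

Observed junctions are compared against the introns of a gene's canonical
transcript.  A junction that reuses one annotated donor and the *next*
intron's acceptor is exon skipping (multi-exon skips are reported as
unclassified, not events); a junction sharing only a donor is an
alternative 3' splice site; sharing only an acceptor, an alternative 5'
splice site, or an alternative first exon when the novel donor lies
upstream of the annotated upstream exon.  Alternative-first-exon events
are classified but excluded from AS-ratio reports by default: they
reflect transcription-start choice (as for the two TMC1 N-termini) rather
than a splicing choice between shared exons.

The replicate-support filter keeps an event only if its alternative
junction has reads in at least `min_replicates` replicates of some group;
the default generalises the 4-of-5 reproducibility rule to ⌈0.8·R⌉.

## The AS ratio

For one event and group, the AS ratio is the pooled proportion
n_alt / (n_alt + n_const) over replicates.  When a side of the event
carries more than one junction — exon skipping has two flanking
constitutive junctions, each of which observes the constitutive isoform
once — the side's count is the rounded mean across its junctions;
summing would double-count the constitutive isoform.  Per-replicate
ratios are reported alongside the pooled value; pooling is used for the
headline number because the pooled proportion is the maximum-likelihood
estimate.

Uncertainty is a 95% Wilson score interval (statsmodels), chosen for its
stability at small counts; the source analysis reports no interval, so
this is an addition, not a reproduction.  Group contrasts (OHC vs IHC)
are descriptive differences of pooled ratios; a two-sided Fisher exact
test on the pooled 2×2 table is available but not used as a filter, and
no multiple-testing correction is applied.

## Protein consequences

The constitutive protein is translated from the annotated CDS (standard
genetic code, table 1; no selenocysteine).  The alternative isoform's
exon set is rebuilt (skipped exon removed, or exon boundary moved to the
alternative splice site; lists of non-overlapping events are applied
5'→3'), and the alternative CDS is re-translated from the unchanged start
codon to the first stop in its frame.  Classification follows the removed
nucleotide count within the CDS: 0 → no coding change; ≡0 mod 3 →
in-frame deletion; otherwise frameshift.  A missing stop before the
transcript end is flagged `stop_lost`; an in-frame deletion whose
junction-created hybrid codon introduces a stop is flagged `stop_gained`.

Deleted ranges are reported **left-aligned**: the first residue at which
the two protein strings diverge anchors the range, so repeats at the
deletion boundary cannot make the representation ambiguous.  Non-codon-
aligned in-frame deletions are reported as the affected codon span with a
`hybrid_codon` flag.  `frameshift_start_aa` is likewise the first altered
residue of the product.

Isoform length ratios are spliced-length quotients reported to three
decimals.  C-terminal homology uses global Needleman–Wunsch alignment
with BLOSUM62, gap open 10 and extension 0.5; identity is the fraction of
alignment columns (gaps included) with identical residues, similarity the
fraction with a positive substitution score.  No scoring scheme is
prescribed by the source analysis for its homology figures, so those
database-sequence numbers are not reproduced here.  Peptide net charge
uses Henderson–Hasselbalch terms with the EMBOSS pKa set (N-term 8.6,
C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1); the
isoelectric point is found by bisection on pH ∈ [0, 14] to |charge| <
1e−4.

## Splice-site conservation

Context windows default to 9 exonic and 9 intronic bases on each side —
wide enough to cover the adjunct sequence typically drawn in splice-site
figures; both are configurable.  Comparison between species is ungapped
and position-by-position (no alignment), with separate donor/acceptor
class match flags; orthologous windows for the second species must be
supplied by the user.

## Primer design

Flanking pairs place the forward primer in the exon immediately upstream
of the event and the reverse primer downstream of the affected region
(within the affected exon's remainder for alternative 3' sites, so a 9-nt
event still yields a compact amplicon); candidates must fall in the Tm
window (default 57–63 °C) and the predicted amplicons of the two isoforms
differ exactly by the removed length.

A discriminating reverse primer's 3' end crosses the target isoform's
splice boundary by `k` nucleotides (default 2).  Mismatch reports count
against the best (minimum-mismatch) ungapped placement of the primer on
each isoform mRNA; a primer is discriminating when it matches its target
perfectly and mismatches the other isoform within the 3'-terminal window
(default 5 nt).  The position weighting is a step function — weight 4
inside the terminal window, 1 outside — encoding the qualitative rule
that 3'-terminal mismatches disrupt priming far more than distal ones;
the exact weights are configurable, as only the qualitative rule is
established.

Melting temperatures are nearest-neighbor estimates (unified parameter
set, via Biopython's `Tm_NN`) at 50 mM monovalent salt and 500 nM primer.
These defaults are a standard modelling choice and are not claimed to
reproduce any particular wet-lab annealing protocol.

## ΔΔCT quantification

ΔCT = CT(target) − CT(reference) matched within a sample; ΔΔCT subtracts
the mean ΔCT of the calibrator segment (default apical); relative
expression is 2^(−ΔΔCT), i.e. amplification efficiency fixed at 2 (no
Pfaffl efficiency correction).  Gradient testing uses unpaired two-sided
Student's t tests per segment pair — classic pooled-variance by default
to match the named test, Welch by flag — at α = 0.05 with no
multiple-testing correction.  Segments come from pooled animals, hence
unpaired.

## Synthetic data

The generator's defaults are the study conditions:

| quantity | default | rationale |
| --- | --- | --- |
| alternative fraction ψ | 0.05 (tmc1-like, tmie-like events), 0.07 (lhfpl5-like) | the ~95:5 and ~93:7 isoform ratios |
| reads per event n | 10,000 | statistical convenience; true per-replicate junction depths are unknown |
| replicates R | 5 | five biological batches |
| groups | IHC, OHC, equal ψ | a single ratio per gene is established; group asymmetry is not fixed numerically |
| CT gradient | 2-fold basal/apical, middle = √2 | the simulated-gradient condition used for power checks |
| CT noise | SD 0.2 cycles | plausible technical noise for SYBR qPCR |
| seed | 20210223 | fixed default; every generator accepts an override |

Fixture geometries are engineered so the published protein consequences
follow exactly: the tmc1-like exon 9 spans codons 213–245 (99 nt) and its
exon-14 alternative acceptor sits 9 nt in (codons 521–523); the
lhfpl5-like alternative acceptor removes codons 166–216 (153 nt) behind a
GC donor; the tmie-like removal is 8 nt at codon 61 (any non-multiple of
3 placed there shifts the frame at residue 61), with the downstream
sequence built jointly in both reading frames so the shifted frame
carries 67 novel residues before its stop — a 127-aa product — while the
constitutive ORF stays open.  Transcript lengths (4,000 / 1,275 / 667 nt)
are chosen so the isoform length ratios come out at 0.973, 0.880, and
0.988; these are fixture engineering, not biology.  Additional sequence
constraints make each alternative acceptor end in AG, make the
deletion-boundary residues distinct (so left-aligned ranges are unique),
and make the upstream exon differ from the removed segment at exactly the
overhang-2 crossing base, reproducing the one-mismatch discrimination
behaviour.  The tmie-like gene is placed on the minus strand to exercise
strand-aware code end to end.  All randomness flows through seeded
generators; constraint satisfaction retries deterministically.

Junction counts are Binomial(n, ψ) per group and replicate for the
alternative junction, with the complement on each constitutive junction;
CT values are baseline − log2(fold) + Gaussian noise.

### What the synthetic data does not emulate

Real junction tables carry alignment artifacts (soft-clips, multimappers,
overhang filters), non-binomial overdispersion between replicates,
coverage that varies along the transcript, and reverse-transcription
length bias; the fixtures have none of these.  Passing tests therefore
demonstrate the correctness of the statistics and sequence logic under
the stated generative model, not robustness to aligner noise.  Real-data
runs also require the user to name the canonical transcript per gene and
to supply orthologous sequence windows for conservation panels.

## Numerical and design notes

* Problem sizes in the test suite (500-run recovery/coverage sweeps,
  1,000-run t-test calibration, 200 randomized consequence variants) were
  chosen to bound Monte-Carlo error while keeping the suite fast.
* Ties in primer-candidate selection break toward the event-proximal
  window closest to the Tm midpoint; ties in mismatch placement break
  toward the leftmost template offset.
* Zero-count AS ratios are flagged undefined rather than raising;
  segment pairs with fewer than two replicates are flagged untestable.
* Degenerate fixture constraints (an unsatisfiable base/stop combination)
  fail loudly after bounded deterministic retries.

## Known limitations

Intron retention and mutually exclusive exons are not detected; BAM/read
level input is out of scope (junction tables are the entry point); no
NMD prediction, transmembrane-topology prediction, or splice-site
strength (PWM/MaxEnt) scoring; Fisher contrasts and Wilson intervals are
desk statistics on pooled counts, not a replacement for a designed
differential-splicing test at scale.
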