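# otosplice

Junction-based analysis of alternative splicing in the hair-cell
mechanotransduction (MT) complex genes *Tmc1*, *Lhfpl5*, and *Tmie*.

Auditory hair cells express previously undescribed splice isoforms of the
MT-complex proteins TMC1, LHFPL5, and TMIE: exon-9 skipping and a 9-nt
alternative 3' splice site in *Tmc1*, an alternative 3' splice site in
*Lhfpl5* exon 2 (with a minor-canonical GC donor), and an alternative 3'
splice site in *Tmie* exon 4 that shifts the reading frame.  `otosplice`
implements the computational side of characterising such isoforms, for
transcriptomicists and auditory neuroscientists working from splice-junction
count tables (e.g. `SJ.out.tab` files from a spliced aligner) and gene
models:

* **event discovery** against a canonical transcript — exon skipping,
  alternative 3'/5' splice sites, alternative first exons — with a
  replicate-reproducibility filter (default: an event must be supported in
  at least ⌈0.8·R⌉ of R biological replicates, the 4-of-5 rule);
* **AS-ratio quantification** per cell-type group.  For an event with
  alternative-junction reads *n*<sub>alt</sub> and constitutive-junction
  reads *n*<sub>const</sub>,

  AS ratio = *n*<sub>alt</sub> / (*n*<sub>alt</sub> + *n*<sub>const</sub>),

  pooled across replicates, with a 95% Wilson score interval and an
  optional Fisher exact contrast between groups (e.g. OHC vs IHC);
* **protein consequences** — re-translation of the alternative isoform
  classifies each event as an in-frame deletion (removed length ≡ 0 mod 3)
  or a frameshift whose product ends at the first stop of the shifted
  frame; plus isoform length ratios, global C-terminal homology
  (Needleman–Wunsch, BLOSUM62), and peptide charge/isoelectric point;
* **splice-site conservation** — strand-aware donor/acceptor context
  windows, GT–AG / GC–AG / noncanonical classing, ungapped positional
  comparison across species;
* **primer design** — event-flanking pairs, and isoform-discriminating
  reverse primers whose 3' end crosses the target isoform's splice
  junction by *k* nucleotides (default 2), scored by position-weighted
  3'-mismatch counts as in allele-specific PCR;
* **qPCR ΔΔC**<sub>T</sub> — relative expression 2^(−ΔΔC_T) against a
  reference gene with Student's t tests along the tonotopic
  (apical–middle–basal) axis;
* **synthetic data** — seeded generators for three gene models that mirror
  the real event geometries, binomial junction counts at specified isoform
  mixtures, and CT values with specified gradients and noise, so the whole
  pipeline is exercisable without any downloads.

## Worked example

```python
from otosplice import (SimulationConfig, make_fixture, detect_events,
                       as_ratio, annotate_consequence)
from otosplice.simulate import simulate_fixture_counts

fx = make_fixture("tmc1_like")                       # seeded synthetic gene
table = simulate_fixture_counts(fx, SimulationConfig())  # 95:5 mixture, 5 reps
for ev in detect_events(fx.gene_model, table):
    cons = annotate_consequence(fx.gene_model.canonical_transcript, ev, fx.genome)
    est = as_ratio(ev, table, "OHC")
    print(f"{ev.event_type:14s} AS ratio (OHC) = {est.ratio:.3f} "
          f"[{est.ci_low:.3f}, {est.ci_high:.3f}]  consequence: {cons.kind}, "
          f"aa {cons.deleted_aa_start}-{cons.deleted_aa_end}")
```

prints

```
exon_skipping  AS ratio (OHC) = 0.050 [0.048, 0.052]  consequence: in_frame_deletion, aa 213-245
alt_3ss        AS ratio (OHC) = 0.049 [0.047, 0.051]  consequence: in_frame_deletion, aa 521-523
```

i.e. both *Tmc1*-like events are recovered at the generating 5% mixture,
exon-9 skipping deletes the 33-residue block spanning amino acids 213–245,
and the 9-nt alternative 3' splice site in exon 14 deletes residues
521–523.

The same pipeline is available from the shell:

```sh
otosplice simulate --out sim --seed 7
otosplice detect   --gtf sim/models.gtf --sj-manifest sim/sj_manifest.tsv --out sim/events.tsv
otosplice quantify --events sim/events.tsv --sj-manifest sim/sj_manifest.tsv --out sim/ratios.tsv
otosplice consequence --gtf sim/models.gtf --fasta sim/genome.fa \
    --events sim/events.tsv --out sim/consequences.tsv
otosplice primers  --gtf sim/models.gtf --fasta sim/genome.fa \
    --events sim/events.tsv --out sim/primers.tsv
otosplice ddct     --ct sim/ct.tsv --out sim/rel_expr.tsv
otosplice report   --indir sim --out sim/report.json
```

Outputs are deterministic for a fixed seed.

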