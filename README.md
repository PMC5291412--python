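# mothmir

De-novo characterization of small RNAs for insects without a reference
genome, plus qPCR reference-gene selection — the complete computational
workflow of a pooled sRNA-seq study in one package.

The pipeline this package implements arose from miRNA profiling of the
oriental fruit moth *Grapholita molesta*, a major orchard pest.  It covers:

* **Read QC** — 3' adapter trimming (adapter dimers flagged), an 18–26 nt
  length window, composition "junk" rules (≥2 N, homopolymer runs ≥7A /
  ≥8C / ≥6G / ≥7T, tandem 2/3/4-mers ≥10/6/5 copies), removal of rRNA /
  tRNA / snoRNA / snRNA / other non-coding classes by reference
  containment, and collapsing to unique reads with a publication-style
  audit table.
* **Conserved miRNA annotation** — matching against known matures with up
  to 3 nt variation at either end and one internal mismatch, miRBase-style
  variant names (`bmo-miR-10-5p_L+1`, `bmo-miR-2b-3p_1ss22GC`), seeds
  (nt 2–8) and abundance classes (low <10, middle 10–1999, high ≥2000
  reads).
* **Novel miRNA discovery** — exact mapping, two candidate precursor
  windows per locus (20 nt up/60 nt down and the reverse), a built-in
  maximum-stability folder (pair energies GC −3, AU −2, GU −1 kcal/mol),
  and the 11-criterion hairpin filter (stem ≥16 bp, ΔG ≤ −15 kcal/mol,
  hairpin ≥50 nt, loop ≤20 nt, bulge and mature-pairing bounds); calls
  need ≥10 reads and are named `gmo-miR-PC-<arm>-<rank>_<count>`.
* **Seed families and conservation** — one family per 7-nt seed and a
  families × species presence matrix.
* **Genomic clustering** — single-linkage chaining of loci at 3/5/10/50 kb
  with cluster-size statistics and within-cluster co-expression.
* **Target prediction and enrichment** — seed sites (8mer/7mer-m8/7mer-A1/
  6mer) filtered by a context-like percentile (≥50) and a gapless duplex
  energy (≤ −10 kcal/mol), intersected; hypergeometric pathway
  over-representation at p ≤ 0.05.
* **qPCR normalization** — standard-curve efficiency
  E% = (10^(−1/slope) − 1)·100, global-mean screening with exact-permutation
  Spearman p, a from-scratch geNorm (M values, iterative ranking, V_{n/n+1}
  with the 0.15 rule), normalization factors and ΔΔCq fold changes
  (2^(−ΔΔCq)) against a calibrator.

Because the original raw library and Cq matrices are not public, the
package ships a synthetic-data module that plants miRNA hairpins in a
genome, emits reads with the realistic contaminant mix, and generates Cq
matrices with stable/unstable genes and known fold changes — every stage is
testable against planted ground truth.  The study's printed summary tables
(audit counts, abundant miRNAs, cluster membership) are included as replay
fixtures for the reporting arithmetic.  See `docs/methods.md` for the
model details and declared simplifications.

## Worked example

The `mothmir` command chains the stages; everything is deterministic given
`--seed`:

```
$ mothmir simulate --seed 7 --out demo/sim
simulate: wrote 2849 reads, 10 hairpins to demo/sim

$ mothmir qc --reads demo/sim/reads.fastq --rfam demo/sim/rfam.fa --out demo/qc
qc: 11 unique reads (36.86 % of raw)

$ mothmir novel --unique demo/qc/unique_reads.fa --genome demo/sim/genome.fa --out demo/novel
novel: called 11 miRNAs (5p/3p ratio 0.5); 0 arm-ambiguous skipped
```

The simulated library plants 10 hairpins (11 mature arms under this seed)
and mixes in ~63 % contaminants, mimicking a real pooled library where only
~37 % of raw reads survive cleaning — hence "36.86 % of raw".  All 11
planted matures are recovered and none besides (the zero-noise guarantee),
each named by arm and rank, e.g.:

```
>gmo-miR-PC-3p-1_112
CTTCTCCTTCTTCCTCCTCTCT
```

The qPCR track runs without any sequence inputs:

```
$ mothmir qpcr --cq demo/sim/cq_matrix.tsv --target demo/sim/cq_target.tsv \
      --calibrator s01 --out demo/qpcr
qpcr: ddCq fold changes written for 8 samples
```

`demo/qpcr/relative_expression.tsv` then holds the target's fold change per
sample versus the calibrator (fold 1.00 at `s01` by construction):

```
        fold_mean   fold_se
s01     1.0013      0.0367
s02     0.1215      0.0020
s03     0.3824      0.0115
```

With noiseless references the planted fold changes are recovered exactly;
the small deviations here are the 0.1-cycle Gaussian Cq noise the generator
plants by default.  The library API mirrors the CLI
(`mothmir.readqc.run_readqc`, `mothmir.novel.call_novel`,
`mothmir.qpcr.genorm_v`, ...).

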