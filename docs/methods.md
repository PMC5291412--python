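# Methods

`mothmir` re-implements the computational workflow of a de-novo small-RNA
(sRNA) characterization study in an insect without a sequenced genome: a
pooled sRNA-seq library is cleaned and collapsed, reads are annotated
against known mature miRNAs, the remainder is screened for novel miRNA
hairpins with an 11-criterion structural filter, and the resulting miRNAs
are analysed for seed-family conservation, genomic clustering and 3'UTR
targets.  A parallel qPCR track selects and validates reference genes
(global-mean screen, geNorm, ΔΔCq).  Because the study's raw reads and Cq
matrices were never deposited, every stage is testable against synthetic
data with planted ground truth; the published summary tables ship with the
package as replay fixtures for the reporting arithmetic.

## Read cleaning and collapsing (`readqc`)

Filter order is adapter → length → junk → Rfam classes → repeats, matching
the order of the published audit table.

* **Adapter.** The 3' adapter is removed at its leftmost full occurrence; a
  read-terminal prefix match (≥ 5 nt) handles adapters truncated by the read
  length.  Empty inserts are adapter dimers.  Untrimmed reads pass through
  and are caught by the 18–26 nt length window.
* **Junk rules.** A read is junk with ≥ 2 N anywhere, a contiguous
  homopolymer run (≥ 7 A, ≥ 8 C, ≥ 6 G, ≥ 7 T), or a contiguous tandem
  repeat of one 2/3/4-mer motif (≥ 10/6/5 full copies; partial trailing
  copies do not count).  Runs and repeats are contiguous by design: counting
  non-contiguous occurrences would flag essentially every read at the A/T
  thresholds.  Rules are evaluated N, A, C, G, T, dimer, trimer, tetramer
  and the first hit is reported, which makes per-rule tallies deterministic.
* **Rfam-class removal.** A read is assigned the category (rRNA, tRNA,
  snoRNA, snRNA, other) of the first labelled reference record that contains
  it as an exact sense-strand substring (configurable ≤ k mismatches).
* **Audit.** Percentages are computed as 100 × category/raw, rounded
  half-up to 2 dp, separately for read totals and distinct sequences.  The
  published audit counts are not internally additive (raw ≠ sum of rows by
  ~3 × 10³ reads), so the calculator takes counts as given; additivity is
  asserted only for tallies this package itself produces.

## Annotation against known matures (`annotate`)

A read matches a reference mature if some end alignment with ≤ 3 nt shift
per end leaves ≤ 1 internal mismatch.  Best match = fewest mismatches, then
smallest total shift, then lexicographically smallest reference id; a read
tied across k references contributes 1/k of its count to each (the origin
of half-integer read counts).  Variant suffixes follow the
`L±n R±n _1ss<pos><ref><read>` grammar with the substitution position
1-based in the read.  Suffixes are invertible except that 5'/3' extensions
add bases absent from the reference; the annotation records those bases, and
`apply_variant` reconstructs the read from them.  The 3-nt end-shift default
is the largest shift observed in the published variant names.  Abundance
classes: low < 10 reads, middle 10–1999, high ≥ 2000 (the printed class
definitions leave exactly 2000 open; it is assigned to "high").

## Novel miRNA discovery (`novel`)

Unannotated reads with ≥ 10 reads (inclusive — the published list's last
entry has exactly 10) are mapped exactly to both strands of the
genome/transcriptome.  For each locus two candidate precursor windows are
cut (20 nt upstream / 60 nt downstream, and the reverse), strand-resolved
and clipped at sequence bounds.

**Folding.** Windows are folded by a self-contained dynamic program that
maximizes stability under a deliberately simple energy model: GC −3,
AU −2, GU −1 kcal/mol per pair, hairpin loops < 3 nt forbidden, no
stacking, loop or multibranch terms.  Ties prefer more pairs, then 5'-most
pairing.  The folder exists so the structural filter runs with no external
binary; the filter itself consumes (structure, ΔG) and accepts external
Vienna-format folds via `read_vienna`, so a thermodynamic folder can be
substituted without touching the criteria.

**Stem-loop parsing.** Because the energy model has no loop penalties,
isolated long-range pairs form freely around a genuine stem.  The hairpin
used for criterion evaluation is therefore the chain of singly-nested pairs
anchored at a hairpin loop, extended outward until a multiloop, with one
parsing rule: a one-sided gap larger than the stem-bulge bound (12 nt) is
crossed only when the pairs beyond it outnumber the gap — a helix that more
than pays for the bulge is a genuine far arm, an isolated enclosing pair is
shed.  Interior gaps are never trimmed, so a 13-nt bulge planted mid-stem
is still measured (and fails criterion 1).  Among hairpins the one whose
stem covers the most mature positions is evaluated; a mature covering no
stem fails outright.

**The 11 criteria** (all must pass): (1) largest one-sided stem bulge
≤ 12 nt; (2) stem pairs ≥ 16; (3) ΔG ≤ −15 kcal/mol (the window's fold
energy); (4) hairpin span ≥ 50 nt; (5) terminal loop ≤ 20 nt; (6) longest
unpaired run in the mature ≤ 8 nt; (7) one-sided ("biased") unpaired mature
positions ≤ 4; (8) one-sided bulge events touching the mature ≤ 2;
(9) unpaired mature positions ≤ 7; (10) paired mature positions ≥ 12;
(11) ≥ 80 % of the mature inside the stem region.  "Biased" is
operationalized as an inter-pair gap with nucleotides on one strand only;
two-sided internal loops count toward (6)/(9) but not (7)/(8) — the
originating pipeline's exact definitions are not public, so these are
declared decisions, not reconstructions.  Two consequences of the energy
model are worth noting: once (2) holds, ΔG ≤ −16 automatically, so (3)
cannot fail alone on a folded structure (its isolation test uses an
externally supplied energy), and a one-sided mature bulge > 8 necessarily
violates (7) and (9) as well.

Passing reads keep the passing window with the lower ΔG, are ranked by
descending count and named `<prefix>-miR-PC-<arm>-<rank>_<count>`; the
count suffix is defined here as the integer read count (the corresponding
published suffixes are library-internal identifiers and do not equal the
printed counts).  Arm = 5p/3p by position of the mature relative to the
loop midpoint; precursors whose two arms both yield called matures are
flagged, and the 5p/3p ratio is computed over single-arm calls.

## Families, clustering, targets

* **Families** are distinct 7-nt seeds (mature nt 2–8).  Cross-species
  presence uses seed identity by default (the study's BLASTn parameters are
  unstated); a full-length-identity rule is available for sensitivity
  analysis.
* **Clustering** chains position-sorted loci per reference sequence with
  end-to-start gaps ≤ d (single linkage, strand ignored, overlap gap
  floored at 0); clusters need ≥ 2 members.  Mean cluster size is reported
  at 1 dp and percent-clustered at 2 dp.  The published member lists at
  3/5/10/50 kb ship as a fixture; replaying them reproduces the printed
  means (3.2/2.9/2.7/2.8) and every 3-kb cluster nests inside a 50-kb one.
  The published percentages imply 166 placed miRNAs, the denominator used
  for the replay.
* **Targets.** Seed sites (6mer core = reverse complement of miRNA nt 2–7,
  typed 8mer/7mer-m8/7mer-A1/6mer) are scored two ways: a context-like
  score (site-type weight + local AU fraction in ±30 nt), kept when its
  within-miRNA percentile is ≥ 50, and a gapless duplex energy under the
  same pair model, kept at ≤ −10 kcal/mol; the prediction is the gene-level
  intersection.  These scorers are declared stand-ins that preserve the
  dual-filter decision logic, not re-implementations of the trained
  TargetScan/miRanda models.  Pathway enrichment is the one-sided
  hypergeometric upper tail, significant at p ≤ 0.05 with no multiplicity
  correction by default (a Benjamini–Hochberg option exists but is off, to
  match the stated decision rule).

## qPCR statistics (`qpcr`)

* **Standard curves.** Cq is regressed on log10(relative amount);
  E% = (10^(−1/slope) − 1) × 100; R² is the squared correlation.  A
  dilution series generated at true efficiency e recovers e exactly at zero
  noise (slope −3.3219 ⇒ 100 %).
* **Global-mean screen.** Spearman rs of each gene's Cq against the
  per-sample mean Cq, average ranks for ties; two-tailed p by exact
  permutation for ≤ 10 samples (chunked enumeration of all n!), t
  approximation above.  Genes with rs > 0 proceed, ranked by rs.  Note the
  screen is only informative when samples share a dominant expression
  component; on the synthetic matrices (independent genes) high-variance
  genes dominate the global mean, so the tests exercise the screen's
  arithmetic and the geNorm stage's recovery, not the screen's recovery.
* **geNorm** is implemented from its published definition rather than
  wrapping the spreadsheet tool: with relative quantities Q = 2^(minCq−Cq),
  V_jk = SD (n−1) of per-sample log2(Q_j/Q_k) and M_j = mean over k≠j; the
  highest-M gene is removed iteratively and the final two genes are
  reported as a tied most-stable pair.  V_{n/n+1} is the SD over samples of
  log2(NF_n/NF_{n+1}) with NF_n the geometric mean of the top-n quantities;
  the recommended set is the smallest n ≥ 2 with V < 0.15.
* **Normalization factor and ΔΔCq.**  Two NF modes: the study's rule — the
  geometric mean of the reference Cq values themselves — and the classic
  quantity-geometric-mean.  The Cq-mode is the default for the validation
  path but is statistically unconventional: unlike an arithmetic Cq mean it
  is only approximately equivariant under common per-sample Cq shifts
  (exactly so for a single reference, which is how the shift-cancellation
  property is tested).  Fold change = 2^(−ΔΔCq) against a calibrator
  sample, mean ± SE over replicates; the calibrator's fold is 1 by
  construction.

## Synthetic data (`synthdata`)

The generator emulates the study design: one pooled library over a genome
with 10 planted hairpins (two clusters — 3 members within 2 kb gaps, 2
within 4 kb — plus singletons, groups separated by 15 kb), mean read depth
100 per mature (Poisson), and a contaminant mix chosen to echo the
published audit: 30 % adapter dimers, 30 % out-of-range lengths, 3 %
Rfam-class fragments, 0.15 % junk, ≈ 37 % mature reads.  Matures are 22 nt
at the arm ends of 30-bp-stem, 10-nt-loop precursors; arm usage is drawn
5p/3p/both at 0.5/0.4/0.1 and a quarter of hairpins sit on the minus
strand.  End shifts (≤ `end_shift_max`, drawn from genomic context so
shifted reads still map) and single substitutions are off by default: the
zero-noise defaults are what exact-recovery guarantees refer to.

Planted hairpins are perfect inverted repeats with purine-only (G/A) 5'
arms, complementary (C/T) 3' arms and an all-A loop.  This alphabet is the
load-bearing trick: arms and loop cannot pair internally, and the planted
register simultaneously gives every arm base its best achievable pair
energy, so the maximum-stability fold always contains the full planted stem
and every planted hairpin passes all 11 criteria (stem ≥ 16, loop ≤ 20,
span ≥ 50).  With fully random alphabets the pair-only energy model happily
rearranges loop and flank bases into alternative pairings and the planted
stem is no longer the optimum — real sRNA data of course has no such
guarantee, which is exactly why passing these tests demonstrates the
machinery (filters, criteria, bookkeeping) and not discovery performance on
thermodynamically realistic structures.

Junk contaminants each violate exactly one named rule (cycled through the
eight rules); Rfam contaminants are substrings of a generated labelled
non-coding reference; length outliers are 15–17 or 27–30 nt.  Raw reads are
emitted as insert + adapter (adapter dimers as the bare adapter) with
constant quality "I".  Labels are conserved: at zero noise the read-QC
category totals equal the planted label counts exactly.

Cq matrices: 12 candidate genes × 8 samples (each sample its own
condition), 6 stable genes (SD 0.1 cycles) and 6 condition-driven genes
(additional per-condition shift, SD 1.5 cycles), plus a validation target
with planted fold changes (2^k, k ∈ {−2..2}, calibrator fold 1) and
five-point 5-fold dilution series at a configurable true efficiency.
Gaussian noise on the cycle scale matches the log-linear qPCR model;
Poisson counts are the simplest count model with known variance for
tolerance arithmetic.  All randomness flows from `rng_seed` through named
substreams, so identical configurations reproduce byte-identical outputs.

## Numerical choices and degenerate inputs

Half-up decimal rounding everywhere a printed-table percentage is
reproduced (banker's rounding would flip some printed values).  Folding
ties prefer pair count, then the 5'-most pairing.  Constant genes are
dropped from the Spearman screen with a warning; zero 3p-only calls leave
the arm ratio undefined (None) rather than raising; clusters of zero leave
the mean cluster size absent.  geNorm requires ≥ 3 genes and reports the
final pair as tied.  Sequences are stored as DNA (U → T) throughout.

## Problem sizes used by the shipped checks

The default test suite and the acceptance script run the full pipeline on
the 10-hairpin, depth-100 synthetic library, verify the folder against
exhaustive structure enumeration for 200–500 random sequences of ≤ 14 nt,
replay all published tables, compare geNorm against a from-definition
recomputation on 4–6-gene toys, run 100 seeded stability-recovery
simulations, and compare the enrichment p-values against exact integer
enumeration over all hypergeometric tables with N ≤ 30.

## Known limitations

The folder is not thermodynamic (no Turner parameters, stacking, dangles or
multibranch penalties) and the target scorers are not the trained models
they stand in for; neither should be used for biological inference on real
data.  Criteria (6)–(9) implement declared operational definitions of
"biased errors/bulges".  The synthetic genome has no repeats, paralogy or
sequencing-quality structure, and substitution noise is limited to one
mismatch per read.  Exact Spearman permutation p-values are limited to
≤ 10 samples.  The conservation module takes tree topology as user input
and performs no phylogenetic inference.
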