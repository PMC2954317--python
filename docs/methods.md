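# Methods

This note documents the models, statistics and design choices behind
`sctrace`, in the order the pipeline runs them.

## Junction references and read matching

A transcript variant is represented by its ordered exon sequences. For
every adjacent exon pair the reference takes 42 nt from the donor end and
42 nt from the acceptor start, giving one 84-nt junction sequence per
(variant, exon pair). Junctions whose flanking exon is shorter than 42 nt
are skipped and counted in a skip report rather than emitted short, so all
retained entries are directly comparable. Entries whose sequence coincides
across variants of the same gene are kept but flagged *shared*; only
unshared ("discriminating") junctions attribute reads to a single variant.

Matching is ungapped substring placement: a 50-nt read is assigned to a
junction when some offset placement has Hamming distance ≤ 4 over the full
read. Indel alignment is deliberately out of scope — the mismatch budget is
defined over the full read, and at toy scale ungapped matching is exact and
auditable (the test suite checks it against a brute-force all-offsets
scan). Two guards are applied:

* **Junction spanning** — the placement must cover the splice point with at
  least `min_overhang` bases (default 1) on each side; otherwise a read
  lying entirely in an exon body could inflate a junction count.
* **Uniqueness** — if the best distance is achieved on two or more
  junctions the read is discarded as ambiguous (on by default).

Both read orientations are searched by default (library strandedness is
treated as unknown); a flag restricts to the forward strand. Read counts
are conserved: assigned + ambiguous + unassigned + skipped = total.

Gene models are loaded from a minimal exon TSV (gene, variant, exon_index,
sequence). A GTF-plus-genome loader is not provided: every in-scope use of
the matcher is at toy scale with explicit exon sequences, and shipping a
genome slice would dwarf the package. This is a known limitation for users
with annotation-only gene models.

## RPM and fold change

RPM = count / library size × 10⁶, where the library size is the sample's
total uniquely aligned reads, supplied as metadata (the junction table's
column sums are a lower bound, never a substitute). No gene- or
transcript-length term is applied, because the single-cell amplification
protocol covers only ~0.5–3 kb from the 3′ end of transcripts, making
length normalisation inappropriate. Fold change floors both sides at a
pseudo-RPM of 0.1 — the detection limit used throughout — so ratios stay
finite; away from the floor log FC is antisymmetric under swapping groups.

## qPCR panels

Ct values live in [0, 40] with 40 the undetected ceiling. Detection is
strict: Ct < 32. Expression uses the standard efficiency-2 (ΔCt)
transform e = 2^(−Ct), with Ct = 40 mapped to e = 0 rather than 2^(−40):
the ceiling encodes "not detected", not a tiny expression value. Normalised
expression divides each gene by its mean over all cells of the panel, so
detected genes have gene-wise mean exactly 1; all-undetected genes are
reported as zeros with a flag instead of dividing by zero.

Gating on Oct4/Sox2/Nanog partitions cells into pluripotent (all three
detected), losing (Oct4 detected, Nanog and/or Sox2 not) and negative
(Oct4 undetected). "High expression" for gating is the Ct < 32 detection
rule; the narrative 19–28 band is used only by the synthetic generator for
drawing marker Ct values. Because published per-stage fractions sometimes
count all cells and sometimes only Oct4-detected cells, the fraction table
reports both denominators.

## Variability

CV = sample (n−1) standard deviation / mean, per feature across cells of
one type; the population-vs-sample choice is not dictated by the source
analyses, so the sample convention is used and stated. Features pass a
platform filter first (RNA-seq: mean RPM > 0.1; qPCR: Ct < 32 in at least
half the cells). RNA-seq features are stratified by mean RPM — high > 10,
1 < mid < 10, low < 1 — with boundary values (exactly 1 or 10, otherwise
unassigned by those strict inequalities) placed in the lower stratum. For
qPCR both the CV of raw Ct values and the CV on the 2^(−Ct) scale are
reported, since the two scales answer different questions (measurement
repeatability vs expression variability). Under Poisson counting noise
CV = 1/√mean, so stratum medians must decrease with expression; this is a
standing test.

The embedding is PCA on log2(RPM + 1) (the transform is a package choice),
zero-variance genes dropped, mean-centred, full SVD. Component signs are
fixed by making each component's largest-magnitude loading positive, so
results are deterministic and invariant to gene/cell order.

## Differential expression

**Gene level.** FC = mean RPM(a) / mean RPM(b) with the 0.1 floor; p from
a two-sided Welch t-test on log2(RPM + 1) across single cells. The test
choice is a package decision (the thresholds FC > 4 / < 0.25, p < 0.01 are
the analysis's defining constants; the test behind them is not): Welch is
robust to unequal variances at n ≈ 9–12 cells per group, and a Wilcoxon
rank-sum alternative is switchable. Genes at or below the floor in both
groups are `not_expressed`. No multiple-testing correction is applied by
default (calls are defined on raw p < 0.01); Benjamini–Hochberg is
available behind a flag. Calls are strict: FC exactly at a threshold is
`unchanged`.

**Variant level.** A variant's expression is the pooled count of its
discriminating junctions; variants with no discriminating junction are
flagged ambiguous and excluded rather than guessed. Expressed means ≥ 5
pooled counts in either sample. The test is a two-sided Fisher exact test
on (count, library − count) per sample — counts here are pooled per
sample, not per cell, so a count-based exact test fits. Gained/lost calls
use raw zeros: ≥ 5 counts on one side and 0 on the other. Calls are
invariant under scaling counts and libraries by a common factor.

**Pluripotency correlation.** r is the Pearson correlation, across cells,
between a gene's log2(RPM + 1) and a per-cell pluripotency score defined as
the mean log2(RPM + 1) of Oct4/Sox2/Nanog. The score definition is a
documented assumption — the quantity the original correlation was computed
against is not specified anywhere — and is the natural single-cell summary
of the three canonical markers.

## Enrichment

All overlap tests are upper-tail hypergeometric: P(X ≥ observed overlap)
for a query of size n against a category of size K in a universe of size
N, with fold = (k/n)/(K/N). The universe is the set of genes detected in
the relevant comparison, not the genome, and is always explicit. Consensus
miRNA targets keep (miRNA, gene) pairs predicted by ≥ 2 of the three
algorithm tables; pooling over a miRNA set is a set union (each gene counts
once; a pair-weighted variant exists). miRNA differential expression is a
two-sided Welch t-test on log2 relative expression across the three
biological replicates per cell type, with FC as the ratio of replicate
means; identical replicate sets give p = 1.

## Synthetic data

The generator's defaults encode the emulated study conditions:

* **Stages** — 9 ICM, 3 epiblast, 2 day-3 Oct4⁺, 3 day-5 Oct4⁺, 2 day-5
  Oct4⁻, 12 ESC cells.
* **Counts** — per-gene negative binomial with shape r (default 2;
  variance = μ + μ²/r; r → ∞ is the Poisson limit), means from a per-stage
  program table on the RPM scale. A lognormal baseline (median 30 RPM,
  σ = 1.6 on the log) spans the low/mid/high strata; each stage gets 40
  program genes raised 8-fold (so ESC-vs-ICM carries 40 planted up and 40
  planted down genes); 30 early-differentiation genes are high only in
  day-5 Oct4⁻ cells, anti-correlated with pluripotency; Oct4/Sox2/Nanog
  are high everywhere except day-5 Oct4⁻.
* **Composition** — program columns are rescaled to 10⁶ "RPM" internally;
  a target depth is drawn uniformly from 0.6–1.1 M reads per cell (the
  implied real depths; an assumption, as the true per-cell depths are
  unpublished), and the recorded library size is the realised column sum,
  keeping RPM derived from the matrix self-consistent. The planted truth
  records fold changes on this realised scale.
* **Dropout** — detection probability is logistic in log2 mean RPM with
  midpoint 0.5 RPM and slope 1.5, mimicking the detection limit of
  low-expressed transcripts; midpoint ≤ 0 disables dropout for controlled
  experiments.
* **Junction reads** — abundances are exact per-junction read counts (so a
  planted 88:35 ratio is exact in truth), offsets uniform over spanning
  placements, substitutions i.i.d. per base.
* **Ct panels** — stage-level marker centres drawn in the 19–28 band,
  per-cell Gaussian noise (default sd 0.5 cycles) clipped to the band;
  lost markers at exactly 40. The default design plants the outgrowth
  narrative: 22/22 ICM triple-positive, 7 of 18 day-3 Oct4-high cells
  losing Nanog and/or Sox2, 11 of 13 day-5, 23/23 ESC.
* **miRNA fixture** — 3 replicates per type with lognormal replicate noise
  (sd 0.2 on log2, ~15% CV, typical TaqMan replicate variability); planted
  ESC/ICM folds include let-7a/e/f/g down 4.5–12-fold, miR-302c up 5-fold,
  miR-367 up 33-fold, and further ≥ 4-fold changes to a total of 51
  differential miRNAs of 330. Target tables: 10 planted miRNAs × 300
  targets in a 10⁴ universe with a 500-gene class. Because pooled targets
  are a set union, planting each miRNA at the requested fold would
  under-deliver (the small class saturates first); the generator therefore
  solves the expected-union-coverage equation for the per-miRNA in-class
  rate that realises the requested *pooled* fold, and errors with the
  achievable range when the request is infeasible.

What the generator does **not** emulate: full-length coverage profiles,
sequencing quality/error-rate structure beyond i.i.d. substitutions,
amplification (WTA) bias, batch effects, doublets, or correlated gene
modules beyond the planted programs. Passing tests therefore demonstrate
the statistics recover planted signals under NB + dropout noise at the
study's sample sizes — not performance on real libraries.

## Numerical and degenerate-input choices

* Strict inequalities at every published threshold (FC, p, Ct, strata).
* CV of a zero-mean feature, fold of an empty query, p of a singleton
  group: returned as NaN flags, never silently dropped or zero-filled.
* Matcher ties are discarded, not broken arbitrarily.
* All generators and the pipeline are deterministic under a single seed;
  the end-to-end bundle is byte-identical across reruns (fixed float
  formatting, sorted JSON keys, digest manifest).

## Problem sizes

Default analyses use 2,000 genes × 31 cells, 330 miRNAs × 10⁴-gene target
universe, and toy junction loci (≤ 20 junctions); these sizes give stable
recovery statistics (sensitivity/FDR estimated over 80 planted genes) while
keeping any run in seconds. All sizes are config fields.
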