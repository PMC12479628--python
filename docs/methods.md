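# Methods

## Scope and model

`srnasig` infers which small-RNA biogenesis pathways are active in a
library from alignment geometry alone. The underlying biological model:

* Dicer cleaves double-stranded precursors into ~20–24 nt duplexes whose
  strands carry 2-nt 3' overhangs on both ends. An opposite-strand read
  pair reproducing that exact geometry is evidence of Dicer processing; the
  per-library rate of such pairs (percent Dicer pairs) separates
  siRNA-producing species from species that lack the pathway.
* Ping Pong amplification produces piRNA pairs on opposite strands whose 5'
  ends overlap by exactly 10 nt, so a sharp excess of the k = 10 bin of the
  5'-5' overlap histogram over neighbouring bins is the Ping Pong
  signature.
* Zucchini-dependent phased processing leaves same-strand trains of piRNAs
  arranged head-to-tail (downstream 5' one base past the upstream 3') with
  uridine as the first nucleotide, so the d = 1 bin of the 1U-restricted
  head-to-tail distance histogram dominates.

All coordinates are 0-based half-open; SAM input (1-based) is converted on
load, BED passes through. 5' nucleotides are reported in RNA space (U).

## Signature statistics

Histogram bins accumulate products of alignment copy numbers, which equals
pair counting for copy-1 input; identical alignments are collapsed first
(the 5' nucleotide is part of alignment identity so 1U filtering survives
collapsing). z-scores use the focal bin against all remaining bins with the
sample (n−1) standard deviation; a zero-variance background (all-equal
bins, including all-zero) yields NaN with an explicit `*_defined` flag
rather than an arbitrary large value. Dicer pairs require both 3' overhangs
to match (the canonical RNase III product); an either-end mode exists for
sensitivity analyses. The percent-Dicer-pairs denominator is the number of
alignments retained in the 15–35 nt window; the pre-filter count is kept in
library metadata and reported alongside. The numerator counts distinct
coordinate pairs once; the copy-weighted count of reads participating in at
least one pair is emitted too, since either convention can be found in
survey work.

## Locus annotation

Loci are seeded as maximal pooled-strand coverage islands at per-base depth
≥ 1. Pre-merge islands supported by fewer than two alignments are discarded
before gap-merging (default `min_island_reads = 2`): a lone stray read is
not a region of interest, and without this rule scattered background within
merge distance of a genuine locus is fused into it, inflating boundaries of
small loci (a single dominant miRNA duplex spans ~24 bp) several-fold. The
seeding depth itself stays at 1 because phased piRNA trains cover each base
exactly once — any per-base depth threshold above 1 would erase them.
Islands within 500 bp are merged, and merged regions are kept at ≥ 1000 RPM
(both defaults follow the survey procedure this package operationalizes;
raw-count thresholds are available behind a flag since sweep descriptions
are sometimes phrased in raw depth). Reads are assigned to loci by
containment of their strand-aware 5' end, so every read counts in exactly
one locus and count conservation holds. The threshold sweep evaluates the
full grid of merge gaps {0, 5, 50, 500, 5000, 50000} bp × expression
thresholds, reporting locus counts and genome-coverage fractions; locus
count is non-increasing in the threshold at fixed gap, and covered bp is
non-decreasing in the gap at threshold 0.

## Size profiles and classification

Per-locus read-length histograms (15–35 nt window) are row-standardized to
mean 0, sd 1 (sample sd; constant rows become zeros and are flagged) and
ordered by hierarchical clustering with Euclidean distance and average
linkage — the common heatmap default; the choice is recorded in output
metadata. Classes are assigned by majority mass: `pirna_like` at ≥ 50% of
reads in 26–30 nt, then `dicer_sized` (18–24 nt), then `degradation_like`
(< 18 nt), else `ambiguous`. miRNA-like and siRNA-like loci are not
separated — size alone cannot distinguish them, and hairpin-based miRNA
discovery is a different tool's job — so both fall under `dicer_sized`. The
strict piRNA mode additionally requires a per-locus Ping Pong z ≥ `z_min`
(default 1.96, i.e. one-sided 2.5%); no canonical value exists for this
cutoff, so it is configurable and echoed in every report.

## Expression

Counts reuse the 5'-containment assignment. Median-of-ratios size factors
follow the standard recipe: per sample, the median over all-positive loci
of count / row geometric mean; when no zero-free locus exists the package
falls back to RPM with a warning. Log2 fold changes use a pseudocount of 1
on group means. PCA operates on log2(normalized + 1) with loci as centered
features and samples as observations; an all-identical input is flagged
degenerate with coordinates at the origin instead of dividing by zero
variance. Dispersion estimation and significance testing are deliberately
out of scope — those belong to dedicated differential-expression tools
consuming the count matrix written here.

## Synthetic data generator

The generator emulates a sequenced small-RNA library as post-clipping,
ungapped alignments against a uniform-random genome (default 4 × 300 kb):

* per class (defaults): 10 loci × 60 biogenesis events, where an event is
  a duplex (mirna/sirna), a Ping Pong pair or unpaired piRNA (pingpong,
  90% paired), or a single read (phased/degradation);
* piRNA lengths 26–30 nt, Dicer lengths 20–24 nt, degradation fragments
  12–17 nt, 300 uniform noise reads of 15–35 nt;
* 1U bias 0.9: the genome base under a biased read's 5' end is overwritten
  (T on the read strand with probability 0.9, otherwise a random non-T
  base), so the bias is recoverable from the genome exactly as for real
  alignments;
* Ping Pong pair sites are placed uniformly at distinct positions within
  the locus span (~40 bp per pair). Incidental overlaps between
  neighbouring sites populate the non-focal histogram bins, as in real
  loci; this keeps the per-locus z-score defined, whereas regularly spaced
  pairs would give a zero-variance background. Every constructed pair still
  overlaps by exactly 10 nt;
* phased trains draw gap 1 with probability 0.85, else uniform 2–9, so the
  distance histogram has a realistic non-empty background;
* loci are placed uniformly without overlap and with ≥ 2 kb spacing so
  merge-gap behaviour is predictable; placement failure after bounded
  retries raises a simulation error rather than silently overlapping.

Reads are emitted as distinct copy-1 alignments; collapsing is left to the
io layer. One seeded generator is threaded through every step, making the
whole bundle (FASTA, coordinate-sorted SAM, truth TSV, config YAML)
byte-reproducible. Expression-level experiments (group profiles → negative
binomial counts) are simulated directly at the count-matrix level, since
read-level simulation adds nothing to tests of normalization, fold-change
and PCA behaviour.

What the generator does **not** model: sequencing error, adapters,
multi-mapping, copy-number spectra fitted to real libraries (per-locus
depth is configurable, not learned), chromatin context, or transposon
structure. Passing tests therefore demonstrate correctness of the geometry,
statistics and bookkeeping under idealized alignments — not robustness to
mapping artefacts of real data.

## Problem sizes and numerical choices

Default verification runs use libraries of roughly 4–20 thousand
alignments over 1.2–1.8 Mb genomes, 40–200 truth loci, and 8-sample count
matrices — sizes at which brute-force oracle comparisons (all-pairs
overlap/phasing/duplex enumeration, per-base coverage scans, cell-by-cell
size-factor recomputation) remain exact and fast. Tolerances: z-scores and
size factors are compared to oracles at machine precision; binomial
quantities (1U fraction) at 99% sampling intervals for the simulated n;
fold-change recovery at ±0.3 log2 units, which absorbs both counting noise
and the small compression introduced when size factors are estimated from a
matrix in which a quarter of loci genuinely shift. Ties in clustering leaf
order are resolved deterministically by scipy; input order does not affect
the partition.
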