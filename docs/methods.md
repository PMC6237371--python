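# Methods

## The discovery model

A vlincRNA is operationalized as a long (≥ 50 kb) contiguous run of
strand-specific transcription outside protein-coding genes. Discovery
works on a single pooled coverage track per strand and applies, in fixed
order: (1) strand-aware removal of covered bases inside gene annotations;
(2) a per-strand read-density threshold; (3) removal of blacklisted bases
on both strands; (4) merging of surviving bases separated by < 500 bp;
(5) merging of the resulting segments separated by < 10 kb; (6) a ≥ 50 kb
length filter. Stage order matters: genes are masked *before* the density
quantile is computed, so gene-derived coverage does not inflate the
threshold.

Numerical choices:

* **Quantile definition.** The density threshold is the depth at 0-based
  rank ⌊q·N⌋ (capped at N−1) of the N covered bases' depth multiset,
  computed per strand (a `joint` option pools both strands). This
  nearest-rank form is exactly reproducible across platforms; for the
  multiset {1,1,1,1,2,2,3,100} at q = 0.75 it yields 3. Bases with depth
  ≥ threshold are kept, i.e. removal is strict `<`.
* **Gap semantics.** "Less than X apart" is strict `<` for both merge
  levels; the far-from-genes rule keeps calls whose gap to every gene is
  ≥ 10 kb, strand-agnostic, with any overlap counting as distance 0.
* **Bridging.** Merging may span gene- or blacklist-masked gaps: masked
  bases were removed from the coverage, not turned into barriers. A
  `bridge_masked=False` option re-subtracts the masks after merging so
  they break segments instead.
* **Determinism.** Call ids are `vlinc_{chrom}_{start}_{strand}`; output is
  coordinate-sorted.

Reciprocal catalog overlap requires the shared bases to cover ≥ `frac`
(default 0.25) of *both* intervals, matching strand only for catalogs
flagged as stranded (public "HumanBlood"-style sets are unstranded).

## Expression profiling

Counting follows the htseq union dialect: a stranded fragment counts for a
call iff it overlaps it (≥ 1 bp) on the same strand, and fragments hitting
two or more same-strand calls are discarded as ambiguous. The
minimal-expression filter keeps autosomal regions with ≥ `min_reads`
(default 100) in ≥ `min_samples` (default 3) samples, both bounds
inclusive.

Normalization is deliberately **not** a DESeq2 reimplementation: size
factors are medians over all-positive regions of count / geometric mean
(falling back to total-count scaling with a warning when no region is
all-positive), and the transform is log2(count/size factor + 1). Output
metadata labels the method as an rld stand-in; clustering structure, not
differential-expression inference, is the supported surface, and
differential testing is out of scope.

Clustering is agglomerative (scipy) on Euclidean distance between samples,
complete linkage by default (single/average/ward selectable); the linkage
was not dictated by the problem, so it is a flag. The cluster count `k` is
a required parameter (model-based selection of k is out of scope). Purity
is (1/N) Σ_clusters max_label |cluster ∩ label|, invariant to label
renaming and equal to 1 only for label-pure clusterings. Subtype-specific
ranking converts normalized values back to the linear scale
(2^x − pseudocount, floored at 0); regions silent in every other subtype
get fold = ∞ and rank first. PCA is a region-centered SVD with the sign of
each component fixed so its largest-magnitude loading is positive.

## Promoter epigenetics

The candidate promoter of a call is the half-open ±10 kb window around its
5′ start (start for +, end for −), clipped at chromosome bounds. Chromatin
segmentations are consumed, never trained: segments whose state is in the
configured H3K4me3-bearing set are kept, merged when separated by < 1 kb,
and retained at length ≥ 400 bp (inclusive). For Roadmap 15-state input the
preset `ROADMAP15_ACTIVE_STATES` = {1, 2, 3, 10, 11} ships with the
package. Refinement assigns each candidate the longest overlapping active
region, breaking length ties by the leftmost start.

Enrichment uses a shuffleBed-style background: each candidate window is
re-placed uniformly at random (chromosome drawn with probability
proportional to its length among those long enough, start uniform),
1000 times by default, and the overlap (≥ 1 bp, strand-agnostic —
chromatin is unstranded) is recounted. Reported are the fold
(observed fraction / mean random fraction, defined as 0 with a warning
when both are 0), a Fisher exact p on [[obs, n−obs], [round(mean_random),
n−round(mean_random)]] (two-sided by default, one-sided selectable), and
the empirical permutation p (1 + #{replicates ≥ observed}) / (shuffles+1),
which is the more defensible statistic and is reported alongside. The 2×2
table built from the rounded mean-random count is this package's
definition, stated explicitly because a background-derived table is a
modelling choice, not data. Enrichment is computed against *candidate*
(±10 kb) promoters; expression-stratified overlap sorts promoters by
expression descending (bin 1 / Q1 = highest), splitting remainders over
the leading bins.

Density profiles bin summed base-coverage in a fixed window around region
centers, normalized to reads-per-million of the track total; bins outside
the genome are missing and excluded from the mean curve, and rows are
ordered by total signal for heatmap export.

## Methylation

WGBS replicates merge by per-CpG count addition (union of positions).
Metaprofiles split the upstream flank, the body and the downstream flank
into ten bins each; body bin edges use exact fractional boundaries rounded
half-up, flank bins are flank/10 each. Bin values are **unweighted** means
of the beta values of covered CpGs (total > 0) — coverage weighting exists
behind a flag — and a bin with no covered CpG is missing, never 0. Rows of
minus-strand regions are reversed so profiles read 5′→3′
(`orient_by_strand=False` keeps genomic orientation; the choice of
orientation is a convention, not a result). 450K probe matrices are
accepted post-normalization (array preprocessing is out of scope); the
probe filters are: detection p > 0.01 in strictly more than 20 % of
samples, non-autosomal location, SNP overlap. Promoter-level values are
plain means over overlapping probes (a probe in two overlapping promoters
contributes to both), and sample correlation uses pairwise-complete
Pearson r with clustering on 1 − r.

## The synthetic-data generator

The generator emulates the *structure* of the real study — its
distributional choices are not claims about the data:

| parameter | default | role |
|---|---|---|
| genome | 3 chromosomes × 10 Mb | autosomal layout |
| planted vlincRNAs | 20, log-uniform 50 kb–1 Mb | discovery truth |
| genes | 40, uniform 5–50 kb | masking / distance filters |
| per-vlincRNA level | log-uniform 8–16 | expression scale |
| coverage | Poisson(level·scale·n_datasets·LogNormal(0, 1.5)) per 200 bp window | burstiness so every transcript has windows above the global Q3 |
| background noise | 0.5 % of windows at depth 1, away from planted features | false-positive pressure on merging |
| counts | NegBin(mean = level·20, dispersion 0.2); 3 subtype-specific regions per subtype boosted 8-fold | subtype structure (4 subtypes × 8 samples) |
| chromatin | "Active" segment (0.6–3 kb) near the 5′ start of each expressed vlincRNA w.p. 0.9; "Quiescent" elsewhere | enrichment truth |
| methylation | CpGs every 500 bp at ~30× coverage; beta ~ Beta(2,8) in active segments, Beta(8,2) elsewhere | hypomethylation truth |

Placement keeps vlincRNAs ≥ 10 kb (scaled) from genes — every plant is
far-from-genes by construction — and mutually separated by ≥ 25 kb so the
10 kb segment merge cannot fuse same-strand plants. The per-window
lognormal burst (σ = 1.5) matters: the Q3 threshold is global per strand,
so without heavy-tailed within-transcript variation, weakly expressed
transcripts would fall entirely below a threshold set by strong ones; with
it, every transcript keeps enough supra-threshold windows (< 10 kb apart)
to be reassembled by the merge stages. A `scaled(factor)` mode shrinks all
bp parameters by one common factor so oracle tests run on ~100 kb genomes
in milliseconds. All stages draw from `default_rng([seed, stage])`, so any
stage is reproducible in isolation.

What the generator does **not** emulate: mappability structure, splicing,
batch-specific library chemistry, copy-number effects, spatially
correlated methylation, and realistic gene density. Passing tests
demonstrate the pipeline's correctness and calibration under the planted
model, not performance on real cohorts.

## Problem sizes and known limitations

The default end-to-end run (30 Mb genome, 32 samples, 1000-shuffle
enrichment, 200-draw null calibration) completes in well under a minute on
one CPU; test-suite oracles use 1 %-scaled genomes. Known limitations:

* The null distribution of **cluster purity** at small N is bounded away
  from the class frequency: with 32 samples, 4 equal classes and a forced
  k = 4 cut, *any* partition has expected purity ≥ 0.344 (balanced random
  partitions: 0.414 ± 0.045), because the expected maximum class share
  within a finite cluster exceeds 1/k. Purity ≈ max class frequency under
  the null holds only asymptotically as N/k grows; at the default
  conditions the measured null purity is ~0.39.
* The empirical permutation p is superuniform in the presence of ties
  (discrete overlap counts), so its rejection rate at α sits slightly
  below α — measured 3–5 % at α = 0.05 in the shipped calibration harness.
* Fisher's p on the observed-vs-rounded-mean table treats the background
  mean as if it were a single observed sample; the permutation p is the
  statistic to trust.
* `shuffle_intervals` rejects placements into the exclusion set rather
  than renormalizing, so extremely dense exclusion sets can exhaust the
  retry cap (an explicit error).
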