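# vlincscope

Discovery and epigenetic profiling of **very long intergenic non-coding
RNAs (vlincRNAs)** — contiguous intergenic transcribed regions of roughly
50 kb to 1 Mb — from strand-specific RNA-seq coverage, with downstream
subtype expression profiling, promoter chromatin-state enrichment and
promoter methylation analysis. The package is aimed at transcriptomics /
regulatory-genomics analysts working with bulk stranded RNA-seq of cancer
cohorts (the motivating setting is childhood acute lymphoblastic leukemia,
cALL, with its pre-B/pre-T immunophenotypes and molecular subtypes such as
high-hyperdiploid and ETV6/RUNX1-rearranged t(12;21)).

## What it computes

**Discovery.** From a pooled strand-specific base-coverage track
(bedGraph pair, from MAPQ ≥ 40 alignments):

1. remove covered bases overlapping protein-coding genes on the same strand;
2. keep bases with read depth ≥ the per-strand Q3 (75 %) density quantile
   (nearest-rank over the covered-base depth multiset);
3. remove blacklisted bases (both strands);
4. merge surviving bases < 500 bp apart, then merge the resulting segments
   < 10 kb apart;
5. call segments of length ≥ 50 kb as stranded vlincRNAs; the
   *far-from-genes* subset keeps calls ≥ 10 kb from any gene on either
   strand.

Calls are compared against public catalogs by **reciprocal overlap**
(shared iff the overlap covers ≥ 25 % of *both* intervals, strand-matched
for stranded catalogs).

**Expression.** Stranded fragment counting (htseq-union style, ambiguous
fragments discarded), the minimal-expression filter (autosomal regions with
≥ 100 reads in ≥ 3 samples), a median-of-ratios + log2 normalization
(a documented stand-in for DESeq2's regularized log), hierarchical
clustering of samples on Euclidean distance, and the **cluster purity**

&nbsp;&nbsp;&nbsp;&nbsp; purity = (1/N) Σ_clusters max_label |cluster ∩ label|

against subtype labels. Subtype-specific vlincRNAs are ranked by the fold
of their mean linear expression in one subtype over the best other subtype.

**Promoter epigenetics.** Candidate promoters are ±10 kb windows around
each call's 5′ start. A ChromHMM-style segmentation is post-processed into
*active regions* (H3K4me3-bearing states, merged < 1 kb, kept ≥ 400 bp);
candidates are refined to the longest overlapping active region. Enrichment
of promoter/active overlap is tested against 1000 length-preserving uniform
shuffles (shuffleBed-style), reporting the fold (observed fraction over
mean random fraction), a Fisher exact p on the observed-vs-rounded-mean
2×2 table, and an empirical permutation p. Overlap can be stratified by
expression (quartiles or 8 bins), and normalized read-density profiles are
computed around promoter centers.

**Methylation.** WGBS CpG count tracks (replicate merging by count
addition), 30-bin metaprofiles (10 bins per upstream flank / body /
downstream flank, unweighted mean beta of covered CpGs, 5′→3′ oriented),
per-promoter mean betas, and 450K-style probe matrices with the standard
filters (detection p > 0.01 in > 20 % of samples, sex chromosomes, SNP
overlap) aggregated to per-promoter means and Pearson-correlation
clustering.

**Synthetic data.** A first-class generator plants ground truth for every
stage: intergenic 50 kb–1 Mb transcribed blocks, background noise,
subtype-structured negative-binomial counts, active chromatin at expressed
promoters and promoter hypomethylation. See `docs/methods.md`.

## Worked example

```bash
python examples/01_discover_vlincs.py
```

```
planted vlincRNAs : 20
calls >= 50 kb    : 20 (median 187.5 kb, range 50-936 kb)
far-from-genes    : 20 calls at least 10 kb from any gene
recovery          : 100% of plants recovered at Jaccard >= 0.8
```

Twenty transcripts were planted on a 3 × 10 Mb genome; the pipeline calls
all twenty with boundaries matching the truth (Jaccard ≥ 0.8), and every
call stays ≥ 10 kb from the simulated genes. `examples/02–04` walk the
expression, promoter-enrichment and methylation stages the same way; e.g.
the enrichment example prints

```
enrichment      : observed 17/20 (85.0%) vs random mean 0.25 (1.26%)
                  fold 67.4, Fisher p 2.6e-08, permutation p 0.001
```

meaning 17 of 20 candidate promoters overlap active chromatin while random
windows of the same sizes almost never do.

The same operations are scriptable from the shell:

```bash
vlincscope simulate --seed 1 --out sim/
vlincscope discover --cov-plus sim/pooled.plus.bedgraph --cov-minus sim/pooled.minus.bedgraph \
    --genes sim/genes.bed --genome sim/genome.tsv -o calls.bed
vlincscope enrich --calls calls.bed --genome sim/genome.tsv --states sim/states.bed \
    --shuffles 1000 --seed 7 -o enrichment.json
```

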