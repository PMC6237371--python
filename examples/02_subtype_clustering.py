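"""Subtype-specific expression profiling and the cluster-purity statistic.

Simulates negative-binomial counts for 4 leukemia subtypes x 8 samples with
3 subtype-specific vlincRNAs planted per subtype (8-fold boost), then runs
the minimal-expression filter, the median-of-ratios log normalization,
hierarchical clustering, and subtype-specific region selection.
"""

import vlincscope as v

cfg = v.SimulationConfig(seed=1)
truth = v.simulate_genome(cfg)
cm, meta = v.simulate_counts(truth)

kept = v.filter_min_expressed(cm, min_reads=100, min_samples=3)
print(f"minimally expressed: {kept.n_regions}/{cm.n_regions} autosomal regions "
      f"with >= 100 reads in >= 3 samples")

norm, size_factors, info = v.normalize_log(kept.counts)
res = v.hierarchical_clusters(norm, k=4)
purity = v.cluster_purity(res.assignment, kept.meta["subtype"])
print(f"cluster purity     : {purity:.2f} using 4 clusters ({info['method']})")

coords, var_frac = v.pca_project(norm)
print(f"PCA                : PC1/PC2 explain {100 * var_frac[0]:.0f}%/{100 * var_frac[1]:.0f}% of variance")

for subtype in ["t(12;21)", "HHD"]:
    ranked = v.subtype_specific(norm, meta.reset_index(), subtype, min_fold=2, top_n=3)
    hits = set(ranked["region"]) & set(truth.specific[subtype])
    print(f"{subtype:>9} specific: top-3 = {list(ranked['region'])} "
          f"({len(hits)}/3 are the planted ones)")
# Purity 1.0 means every cluster is a single subtype; the top-ranked
# fold-change regions recover the planted subtype-specific vlincRNAs.
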