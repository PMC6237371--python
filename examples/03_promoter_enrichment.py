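"""Promoter chromatin-state enrichment with a shuffle background.

Expressed planted vlincRNAs get an "Active" chromatin segment near their 5'
start with probability 0.9.  The pipeline builds ±10 kb candidate promoters,
post-processes the segmentation into active regions (merge < 1 kb, keep
>= 400 bp), refines promoters to the longest overlapping active region, and
tests overlap enrichment against 999 length-preserving uniform shuffles.
"""

import vlincscope as v

cfg = v.SimulationConfig(seed=1)
truth = v.simulate_genome(cfg)
states, _ = v.simulate_chromatin_and_meth(truth)

params = v.PromoterParams(n_shuffles=999, active_states=frozenset({"Active"}))
active = v.active_regions(states, params)
print(f"active regions  : {len(active)} (H3K4me3-state segments, merged, >= 400 bp)")

pset = v.candidate_promoters(truth.vlincs_as_intervalset(), truth.layout)
refined = v.refine_promoters(pset, active)
print(f"refined         : {refined.n_refined}/{len(refined)} candidate promoters "
      f"({100 * refined.refined_fraction:.0f}%) overlap an active region")

res = v.overlap_enrichment(pset, active, truth.layout, params, seed=7)
print(f"enrichment      : observed {res.n_obs_overlap}/{res.n} "
      f"({100 * res.obs_fraction:.1f}%) vs random mean {res.mean_random:.2f} "
      f"({100 * res.mean_random_fraction:.2f}%)")
print(f"                  fold {res.fold:.1f}, Fisher p {res.fisher_p:.2g}, "
      f"permutation p {res.permutation_p:.3g}")

# expression-stratified view: bin 1 = highest-expressed vlincRNAs
expr = truth.vlincs["level"]
bins = v.expression_stratified_overlap(pset, active, expr, n_bins=4)
print("quartile overlap:", [f"Q{int(b)}={f:.2f}" for b, f in zip(bins["bin"], bins["fraction"])])
# A fold well above 1 with a small permutation p says active chromatin sits
# at vlincRNA promoters far more often than at random genomic windows.
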