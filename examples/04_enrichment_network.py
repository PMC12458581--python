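"""Gene-set enrichment and the pathway-overlap permutation test.

ORA is the hypergeometric tail of hit/set overlap; preranked GSEA is the
weighted running-sum statistic; and the permutation test asks whether two
exposures' enriched-pathway lists share more members than chance, fitting
a normal to 10,000 permuted overlaps.
"""

import numpy as np

from liveraging import gsea_preranked, ora, pathway_overlap_test

universe = {f"gene{i:03d}" for i in range(500)}
pathway = {f"gene{i:03d}" for i in range(40)}
hits = {f"gene{i:03d}" for i in range(60)}  # first 40 are the pathway
res = ora(hits, pathway, universe)
print(f"ORA: {res.k}/{res.n} hits in a {res.K}-gene set "
      f"(fold={res.fold_enrichment:.1f}, p={res.p_value:.2e})")

rng = np.random.default_rng(0)
ranked = [f"gene{i:03d}" for i in range(200)]
scores = sorted(rng.normal(size=200), reverse=True)
rec = gsea_preranked(ranked, scores, set(ranked[:15]), n_perm=1000, seed=1)
print(f"GSEA: ES={rec.es:.3f}, NES={rec.nes:.2f}, p={rec.p_value:.3g}, "
      f"{len(rec.core_genes)} leading-edge genes")

pathways = {f"P{i:03d}" for i in range(300)}
enriched_a = {f"P{i:03d}" for i in range(40)}
enriched_b = {f"P{i:03d}" for i in range(20, 60)}  # 20 shared
res = pathway_overlap_test(enriched_a, enriched_b, pathways, n_perm=10_000, seed=2)
print(f"pathway overlap: observed={res.observed}, null mean={res.perm_mean:.2f} "
      f"(sd {res.perm_sd:.2f}), z={res.z:.1f}, p={res.p_value:.2e}")
# A z far above 0 says the two exposures converge on the same pathways far
# beyond what drawing pathway lists at random would produce.
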