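"""Rank all proteins by causal distance to a seed list and validate by GSEA.

Uses one pathway's members as high-confidence seeds, ranks every protein by
its weighted shortest-path distance to the closest seed, then checks with a
running-sum enrichment score that the seeds themselves (positive control)
top the ranking while random sets do not.
"""

import numpy as np

from causalprox.ranking import gsea, seed_distance_ranking
from causalprox.synthetic import SyntheticSpec, generate

graph, truth = generate(SyntheticSpec(seed=1))
seeds = sorted(truth.pathway_memberships["PW0"])
ranked = seed_distance_ranking(graph, seeds)

print(f"ranked {len(ranked)} proteins; top 5:")
for r in ranked.records[:5]:
    print(f"  #{r.rank} {r.gene} d={r.seed_distance:.2f} via {r.nearest_seed}")

pos = gsea(ranked, set(seeds), n_perm=500, seed=2, set_name="seeds")
rng = np.random.default_rng(0)
rand = gsea(ranked, set(rng.choice(ranked.genes, size=15, replace=False)),
            n_perm=500, seed=3, set_name="random")
print(f"GSEA seeds:  es={pos.es:+.3f} p={pos.p:.3g}")
print(f"GSEA random: es={rand.es:+.3f} p={rand.p:.3g}")
# the seed set sits at distance 0, so its running sum climbs straight to
# es = +1; a random set drifts near 0 with a non-significant permutation p.
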