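"""Compare path-based proximity against heat-diffusion propagation.

Both methods score how strongly nodes communicate with a phenotype; the
diffusion kernel works on the symmetrized score-weighted graph and thus
discards edge direction and regulatory sign, which the path-based score
keeps.  Top-20 overlap quantifies how similar the two rankings are.
"""

import causalprox as cp
from causalprox.synthetic import SyntheticSpec, generate

graph, truth = generate(SyntheticSpec(seed=5))
res = cp.proximity_scores(graph, ["PHEN_0"])
prox_scores = {r.source: -r.z for r in res}  # higher = closer

diff = cp.heat_diffuse(graph, ["PHEN_0"], t=0.3)
print(f"total heat after diffusion: {sum(diff.scores.values()):.9f} "
      "(conserved, = 1 seed)")

shared = {n: diff.scores[n] for n in prox_scores}
report = cp.compare_rankings(prox_scores, shared, k=20)
print(f"top-20 Jaccard overlap: {report['jaccard_topk']:.2f}")
print(f"Spearman rank correlation: {report['spearman']:.2f}")
planted = truth.planted_proximal["PHEN_0"]
top_prox = {n for n, _ in sorted(prox_scores.items(), key=lambda x: -x[1])[:20]}
print(f"planted regulators in proximity top-20: {len(planted & top_prox)}/10")
# the two methods agree far beyond chance (random 20-of-300 sets overlap
# with Jaccard ~0.07), but only the path-based score also reports the net
# regulatory sign of each source-phenotype connection.
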