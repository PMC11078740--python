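# Methods

## The causal graph model

The core container is a directed multigraph over typed entities (protein,
complex, small molecule, phenotype, stimulus, fusion protein, protein
family, miRNA, other). An edge `A → B` carries a regulatory effect in
{+1, −1, 0} (up-regulates, down-regulates, unknown/complex-formation) and a
trust score in [0.1, 1.0]; scores outside that range are rejected (strict
mode) or skipped with a tally (lenient mode). Parallel edges between the
same ordered pair are kept when they differ in effect or mechanism:
conflicting literature evidence is represented, not collapsed. Compound
effect labels from SIGNOR-style files map to sign by prefix
(`up-regulates*` → +1, `down-regulates*` → −1, everything else → 0); the
mapping is a plain table and user-replaceable. Fusion proteins and chemical
stimuli participate in paths as ordinary nodes — nothing in the scoring
model distinguishes them.

## Proximity scoring

For a target node *t* the scorer enumerates every simple directed path of
at most `max_steps` edges that ends at *t* and starts at a protein- or
complex-type node. The default bound is 3 edges — the stricter reading of a
"shorter than four steps" horizon — with 4 available as a preset; beyond
that, path counts explode and the distance signal washes out. Only simple
paths are counted (cycles would make the path population unbounded), and
every distinct edge sequence counts once, so two parallel edges of opposite
sign yield two paths.

Each edge costs `1 − score` (default; bounded in [0, 0.9], zero cost only
at full trust) or `−ln(score)`; both are strictly decreasing in trust. A
path's distance is the sum of its edge costs and its net sign the product
of edge effects (0 if any effect is unknown).

All path distances into *t* form the target's distance distribution
(μ_t, σ_t with sample sd). Normalizing per target is what makes scores
comparable across targets: hub phenotypes collect many short paths, so raw
distances mean nothing absolutely. A source's Z is computed from its best
(minimum-distance) path; significance is `z < z_threshold` (default −1.96,
one-sided p < 0.05). When tied-best paths disagree in sign the pair is
reported `mixed`. Targets with fewer than two paths or zero spread have no
defined Z; they are excluded from records and listed in a QC field rather
than silently scored. Z-scores are assigned per path, so within each target
the pooled path Z's have mean 0 and sample sd 1 by construction — the test
suite asserts this to 1e−9 as a pipeline integrity check.

## Enrichment statistics

*ORA*: one-sided Fisher exact test per term via the upper hypergeometric
tail, background defaulting to all protein-type nodes of the loaded graph;
Bonferroni correction by default for pathway panels (exact `min(1, m·p)`),
Benjamini–Hochberg optionally for exploratory phenotype scans.

*Membership extension / PPA*: all bounded paths into any curated member of
a pathway are pooled into one distribution; a non-member is added to the
extended membership when its best path's Z clears the threshold. PPA is ORA
on the extended sets, with hits flagged curated vs proximity-added. A
degenerate pooled distribution leaves the membership unchanged, flagged.

*Phenotype t-test*: Welch two-sample, one-sided ("query closer", i.e.
lower Z), comparing query proteins' best-path Z-values against all other
scored proteins per phenotype. The choice of Z-scores as the compared
sample (rather than raw distances or counts) is a design decision of this
package: Z's are the scale on which targets are comparable. Groups under 3
records are skipped with a flag. Direction is the consensus of the query's
net path signs (up / down / mixed).

*Random-list p*: draw `n_lists` uniform protein lists matched to the query
size and report the add-one estimator
`p = (#{count ≥ observed} + 1) / (n_lists + 1)`, where count = number of
list members significantly close to the phenotype. The pseudocount keeps p
off zero under finite resampling.

## Connectivity null model

The observed statistic is the number of directed edges with both endpoints
in the query (parallel edges counted once by default — connectivity is
about links, not evidence lines; a flag restores multiplicity counting).
The null rewires the graph by directed double edge swaps: two edges
`a→b, c→d` exchange targets to `a→d, c→b`, which preserves every node's in-
and out-degree exactly; swaps creating self-loops or duplicating an
existing (source, target, effect) edge are rejected. Attempted swaps
default to 10·|E|. Attributes travel with the rewired edge, so the
(effect, score) multiset is conserved exactly. Both an add-one empirical p
(floored at 1/(n+1)) and a Gaussian upper-tail parametric p are reported:
with 1000 replicates the empirical p cannot go below ~1e−3, so extreme
connectivity is expressible only parametrically.

`connectivity_calibration` shares one rewired ensemble across calibration
replicates. The null ensemble does not depend on the query, so each
replicate's p has the same marginal distribution as a fresh call; sharing
makes 500-replicate uniformity sweeps run in seconds. Replicates are then
weakly dependent, which the KS check tolerates.

## Communities and bridges

Community detection runs walktrap (random-walk agglomeration, default walk
length 4) on the undirected projection with summed edge scores as weights,
cutting the merge dendrogram at maximal modularity; direction and sign are
ignored because the underlying algorithm is undirected. The bridge builder
returns all direct query–query edges plus any non-query node adjacent (in
either direction) to ≥ 2 distinct query members together with its
query-incident edges; bridge–bridge edges are excluded and query members
left without edges are flagged isolated.

## Ranking and GSEA

Seed-distance ranking uses unbounded weighted shortest paths (Dijkstra per
seed), taking by default the minimum of the seed→gene and gene→seed
orientations — the appropriate default when no orientation is stated for
"causal distance" — with pure downstream/upstream modes and an optional hop
bound (synchronous Bellman–Ford) available. Unreachable proteins get
infinity and rank after all finite entries; all ties break
lexicographically so output is deterministic. Note that full-trust
(score 1.0) edges cost 0, so non-seed genes can legitimately tie seeds at
distance 0.

GSEA uses the unweighted running-sum statistic: +1/n_hits at set members,
−1/n_misses elsewhere; the enrichment score is the signed extremum, so
|es| ≤ 1 and a set occupying the top block scores exactly +1. The
permutation null redraws same-size gene sets; p is one-sided *within the
same-sign portion of the null* — against the full null the p of a random
set would concentrate below 0.5 rather than be uniform. NES divides es by
the mean |null es| of the same sign. Only the unweighted (exponent 0)
statistic is implemented: the seed-distance metric has no natural weighting
scale.

## Heat diffusion

`exp(−t L)` applied to the seed indicator vector, with L the combinatorial
Laplacian of the symmetrized score-weighted graph (dense `expm` by default,
eigendecomposition as an agreeing alternative, tolerance 1e−6 on ≤ 100
nodes in tests). This kernel is non-negative and conserves total heat to
1e−9; the optional normalized Laplacian does not conserve heat and is off
by default. Default `t = 0.1`; larger t flattens scores monotonically.
Signs cannot be represented in this kernel — an intrinsic limitation of
diffusion that path-based proximity does not share, and the reason the
comparison module reports only ranking agreement.

## Synthetic benchmarks

The generator emulates a curated causal interactome: `n_proteins`
background proteins wired as a directed Erdős–Rényi graph at density 0.008
(mean in/out degree ≈ 4, the sparsity regime of curated signaling
resources), phenotypes as pure sinks (terminal readouts), and trust scores
drawn from the categorical levels {0.1, …, 1.0} with mid-range-peaked
weights (mode at 0.4–0.5, ~3% of edges at 0.9–1.0) — curated confidence
concentrates in the middle tiers, and this shape also gives path-distance
distributions a well-defined bulk against which genuinely short high-trust
paths stand out. Edge signs are −1 with probability `sign_mix` (default
0.3). Planted structure: a proximal module (10 proteins, one score-0.9 edge
each to the first phenotype by default; longer planted paths insert
dedicated relay nodes recorded in the ground truth), a dense module
(internal density 0.5 vs 0.008 background), and 8 satellite regulators per
pathway attached by one score-0.9 edge to a member. `null_spec` disables
all planting for calibration. Generation is byte-identical given spec +
seed.

What the synthetic networks do **not** emulate: scale-free degree
distributions, correlated edge placement (real pathways share hubs),
mechanism annotations, or realistic phenotype fan-in. Passing the planted
benchmarks therefore shows the *procedures* behave as specified under
known ground truth — not that any particular biological list will score
significantly on a real interactome.

## Problem sizes and numerical choices

Tests and the acceptance script run on 500-protein networks (~2000 edges),
10–20 generator seeds per claim, 100–200 rewirings or permutations per
null, and 200-replicate-or-more calibration sweeps; these sizes give stable
rates while keeping the full suite in the low minutes. Calibration of the
phenotype procedures uses a denser null network (density 0.016) and
100–150-gene queries: empirical-count p-values are discrete, and
calibration can only be assessed where the count statistic has enough
spread. Fisher p's are validated against integer-arithmetic tail summation
to 1e−12; rewiring invariants are checked exactly; Z-normalization to
1e−9. Degenerate cases (zero-spread distributions, unswappable graphs,
empty queries) are flagged or raised explicitly rather than silently
defaulted.

## Known limitations

* Path enumeration is exponential in `max_steps`; the default bound of 3
  is also what keeps the statistic local and interpretable.
* Multigraph parallel paths through the same node sequence are counted
  once per distinct edge sequence; no deduplication by node set.
* The empirical connectivity p is floored by the replicate count; cite the
  parametric tail for extreme observations, with its Gaussian assumption
  stated.
* Complex/family membership expansion is supported only through
  user-supplied maps; no identifier translation is attempted.
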