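"""Connectivity significance, degree-preserving nulls, communities, bridges.

The connectivity test asks whether a protein list is more densely
interlinked than expected: the observed number of direct causal edges among
the list is compared with the same count on networks rewired by directed
double edge swaps that conserve every node's in- and out-degree.  Both an
add-one empirical p and a Gaussian upper-tail parametric p are reported --
finite replicate counts bound the empirical p from below (1000 replicates
cannot go under ~1e-3), so extreme significance is only expressible
parametrically.

Community structure is found with walktrap-style random-walk agglomeration
on the score-weighted undirected projection, and the bridge builder
reconstructs "connect + add bridge proteins" subnetworks: direct edges among
a query plus any outside node touching at least two query members.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import igraph as ig
import numpy as np
from scipy import stats

from causalprox.graph_model import CausalEdge, CausalGraph, induced_subgraph

logger = logging.getLogger(__name__)


@dataclass
class NullSummary:
    """Observed statistic against a randomized-network null distribution."""

    observed: float
    null_values: list[float]
    null_mean: float
    null_sd: float
    p_empirical: float
    p_parametric: float  # nan when null_sd == 0
    n_random: int
    seed: int


@dataclass
class CommunityPartition:
    membership: dict[str, int]
    modularity: float
    n_communities: int


@dataclass
class BridgeNetwork:
    """Result of the bridge-protein subnetwork construction."""

    graph: CausalGraph
    bridges: set[str]
    isolated_query: set[str]  # query members with no edge in the subnetwork


def direct_edge_count(
    graph: CausalGraph, nodes: Iterable[str], count_multiplicity: bool = False
) -> int:
    """Directed edges with both endpoints in ``nodes``.

    Parallel edges between the same ordered pair count once by default
    (connectivity is about links, not evidence lines); set
    ``count_multiplicity`` to count every parallel edge.
    """
    wanted = set(nodes)
    unknown = wanted - set(graph.entities)
    if unknown:
        logger.warning("ignoring %d unknown node ids", len(unknown))
        wanted -= unknown
    if count_multiplicity:
        return sum(
            1 for e in graph.edges if e.source in wanted and e.target in wanted
        )
    pairs = {
        (e.source, e.target)
        for e in graph.edges
        if e.source in wanted and e.target in wanted
    }
    return len(pairs)


def randomize_preserving_degree(
    graph: CausalGraph, seed: int, n_swap_multiplier: int = 10
) -> CausalGraph:
    """Rewire by directed double edge swaps conserving in/out degrees.

    Picks two edges (a->b, c->d) and swaps their targets to (a->d, c->b);
    swaps creating self-loops or duplicating an existing (source, target,
    effect) edge are rejected.  Edge attributes travel with the rewired
    edge.  ``n_swap_multiplier * |E|`` swaps are attempted.
    """
    if graph.n_edges < 2:
        logger.warning("graph too small to rewire; returning copy")
        return graph.copy()
    if n_swap_multiplier < 1:
        raise ValueError("n_swap_multiplier must be >= 1")
    rng = np.random.default_rng(seed)
    edges = list(graph.edges)
    occupancy = Counter((e.source, e.target, e.effect) for e in edges)
    m = len(edges)
    n_attempts = n_swap_multiplier * m
    picks = rng.integers(0, m, size=(n_attempts, 2))
    swapped = 0
    for i, j in picks:
        if i == j:
            continue
        e1, e2 = edges[i], edges[j]
        # new edges a->d, c->b
        if e1.source == e2.target or e2.source == e1.target:
            continue  # would create a self-loop
        k1 = (e1.source, e2.target, e1.effect)
        k2 = (e2.source, e1.target, e2.effect)
        if occupancy[k1] or occupancy[k2]:
            continue  # would duplicate an existing edge
        occupancy[(e1.source, e1.target, e1.effect)] -= 1
        occupancy[(e2.source, e2.target, e2.effect)] -= 1
        occupancy[k1] += 1
        occupancy[k2] += 1
        edges[i] = CausalEdge(
            source=e1.source, target=e2.target, effect=e1.effect,
            score=e1.score, mechanism=e1.mechanism, pmids=e1.pmids,
        )
        edges[j] = CausalEdge(
            source=e2.source, target=e1.target, effect=e2.effect,
            score=e2.score, mechanism=e2.mechanism, pmids=e2.pmids,
        )
        swapped += 1
    if swapped == 0:
        logger.warning("no legal swap found; returning copy")
    out = CausalGraph()
    for ent in graph.entities.values():
        out.add_entity(ent)
    for e in edges:
        out.add_edge(e, dedupe=False)
    return out


def _empirical_p(null_values: np.ndarray, observed: float) -> float:
    return (int(np.sum(null_values >= observed)) + 1) / (len(null_values) + 1)


def connectivity_pvalue(
    graph: CausalGraph,
    nodes: Iterable[str],
    n_random: int = 1000,
    seed: int = 0,
    n_swap_multiplier: int = 10,
    count_multiplicity: bool = False,
) -> NullSummary:
    """Significance of the direct-edge count among ``nodes`` against the
    degree/direction-preserving rewiring null."""
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    node_set = set(nodes)
    observed = direct_edge_count(graph, node_set, count_multiplicity)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_random)
    null_values = np.empty(n_random)
    for i, s in enumerate(sub_seeds):
        rand = randomize_preserving_degree(graph, int(s), n_swap_multiplier)
        null_values[i] = direct_edge_count(rand, node_set, count_multiplicity)
    null_mean = float(np.mean(null_values))
    null_sd = float(np.std(null_values, ddof=1))
    if null_sd == 0.0:
        logger.warning("degenerate null (sd = 0): parametric p undefined")
        p_par = float("nan")
    else:
        p_par = float(stats.norm.sf((observed - null_mean) / null_sd))
    return NullSummary(
        observed=float(observed),
        null_values=null_values.tolist(),
        null_mean=null_mean,
        null_sd=null_sd,
        p_empirical=_empirical_p(null_values, observed),
        p_parametric=p_par,
        n_random=n_random,
        seed=seed,
    )


def connectivity_calibration(
    graph: CausalGraph,
    set_size: int,
    n_random: int = 100,
    n_replicates: int = 500,
    seed: int = 0,
) -> list[float]:
    """Empirical connectivity p-values for uniformly drawn node sets.

    Shares one rewired ensemble across replicates (the null ensemble does
    not depend on the query), which makes large calibration sweeps cheap;
    each replicate's p is marginally the same as a fresh
    :func:`connectivity_pvalue` call.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.entities)
    index = {n: i for i, n in enumerate(nodes)}
    prot_idx = np.array([index[p] for p in graph.proteins])

    def pair_arrays(g: CausalGraph) -> tuple[np.ndarray, np.ndarray]:
        pairs = sorted({(index[e.source], index[e.target]) for e in g.edges})
        arr = np.array(pairs, dtype=np.int64)
        return arr[:, 0], arr[:, 1]

    ensemble = []
    for _ in range(n_random):
        rand = randomize_preserving_degree(graph, int(rng.integers(0, 2**31 - 1)))
        ensemble.append(pair_arrays(rand))
    obs_src, obs_tgt = pair_arrays(graph)
    pvals = []
    for _ in range(n_replicates):
        member = np.zeros(len(nodes), dtype=bool)
        member[rng.choice(prot_idx, size=set_size, replace=False)] = True
        obs = int(np.count_nonzero(member[obs_src] & member[obs_tgt]))
        nulls = np.array(
            [
                int(np.count_nonzero(member[s] & member[t]))
                for s, t in ensemble
            ]
        )
        pvals.append(_empirical_p(nulls, obs))
    return pvals


def detect_communities(graph: CausalGraph, walk_length: int = 4) -> CommunityPartition:
    """Walktrap random-walk communities on the score-weighted undirected
    projection; the partition maximizing modularity along the merge
    dendrogram is returned.  Parallel and antiparallel edge weights sum."""
    if graph.n_nodes == 0:
        raise ValueError("graph is empty")
    nodes = sorted(graph.entities)
    index = {n: i for i, n in enumerate(nodes)}
    weights: dict[tuple[int, int], float] = {}
    for e in graph.edges:
        i, j = index[e.source], index[e.target]
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        weights[key] = weights.get(key, 0.0) + e.score
    g = ig.Graph(n=len(nodes), edges=list(weights), directed=False)
    if weights:
        g.es["weight"] = list(weights.values())
        dendro = g.community_walktrap(weights="weight", steps=walk_length)
    else:
        dendro = g.community_walktrap(steps=walk_length)
    clustering = dendro.as_clustering()
    membership = {n: clustering.membership[index[n]] for n in nodes}
    return CommunityPartition(
        membership=membership,
        modularity=float(clustering.modularity or 0.0),
        n_communities=len(clustering),
    )


def connect_with_bridges(graph: CausalGraph, query: Iterable[str]) -> BridgeNetwork:
    """Subnetwork of direct query-query edges plus bridge proteins.

    A bridge is a non-query node adjacent (either direction) to at least two
    distinct query members; only its query-incident edges are kept, and no
    bridge-bridge edges are included.  Query members left without any edge
    are flagged isolated.
    """
    q = set(query) & set(graph.entities)
    neighbor_query: dict[str, set[str]] = {}
    for e in graph.edges:
        if e.source in q and e.target not in q:
            neighbor_query.setdefault(e.target, set()).add(e.source)
        elif e.target in q and e.source not in q:
            neighbor_query.setdefault(e.source, set()).add(e.target)
    bridges = {b for b, qs in neighbor_query.items() if len(qs) >= 2}
    sub = CausalGraph()
    for nid in sorted(q | bridges):
        sub.add_entity(graph.entities[nid])
    touched: set[str] = set()
    for e in graph.edges:
        in_q_src, in_q_tgt = e.source in q, e.target in q
        keep = (in_q_src and in_q_tgt) or (
            (in_q_src and e.target in bridges) or (in_q_tgt and e.source in bridges)
        )
        if keep:
            sub.add_edge(e, dedupe=False)
            touched.add(e.source)
            touched.add(e.target)
    isolated = q - touched
    if isolated:
        logger.warning("%d query members isolated in bridge subnetwork", len(isolated))
    return BridgeNetwork(graph=sub, bridges=bridges, isolated_query=isolated)
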