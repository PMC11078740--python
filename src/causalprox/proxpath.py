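"""Bounded causal-path enumeration and per-target proximity Z-scores.

The proximity procedure scores how strongly a protein's activity can reach a
target node (typically a phenotype) along short causal paths:

1. enumerate every simple directed path of at most ``max_steps`` edges from
   each eligible source to the target, weighting each edge by a cost that
   decreases with its trust score;
2. pool all path distances into the target's distance distribution and
   express each path as a Z-score within it;
3. call a source significantly close when the Z of its best (minimum
   distance) path falls below the threshold (default -1.96, i.e. p < 0.05
   one-sided).

Z-normalization per target corrects for how central the target is in the
graph: hub phenotypes collect many short paths, so raw distances are not
comparable across targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from causalprox.graph_model import CausalEdge, CausalGraph

#: entity types eligible as path sources by default (phenotype->phenotype
#: paths are excluded: the method scores protein-to-phenotype regulation).
DEFAULT_SOURCE_TYPES = ("protein", "complex")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ProxConfig:
    """Tunable parameters of the proximity scoring.

    max_steps
        Maximum number of edges per path.  Default 3 (the stricter reading
        of a four-step horizon); 4 is a sensible alternative preset.
    cost_model
        ``one_minus_score`` (cost = 1 - score, bounded in [0, 0.9]) or
        ``neg_log_score`` (cost = -ln(score)).
    z_threshold
        Significance cut on the per-pair Z; must be negative.
    allow_zero_sign_edges
        Whether edges with unknown sign (effect 0) may appear in paths.
    source_types
        Entity types eligible as path sources.
    """

    max_steps: int = 3
    cost_model: Literal["one_minus_score", "neg_log_score"] = "one_minus_score"
    z_threshold: float = -1.96
    allow_zero_sign_edges: bool = True
    source_types: tuple[str, ...] = DEFAULT_SOURCE_TYPES

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ConfigurationError("max_steps must be >= 1")
        if self.z_threshold >= 0:
            raise ConfigurationError("z_threshold must be negative")
        if self.cost_model not in ("one_minus_score", "neg_log_score"):
            raise ConfigurationError(f"unknown cost_model {self.cost_model!r}")


@dataclass(frozen=True)
class CausalPath:
    """An ordered simple chain of causal edges with its weighted distance."""

    edges: tuple[CausalEdge, ...]
    source: str
    target: str
    n_steps: int
    distance: float
    net_sign: int  # product of effects, 0 if any edge has unknown sign

    @property
    def nodes(self) -> tuple[str, ...]:
        return (self.edges[0].source,) + tuple(e.target for e in self.edges)


@dataclass(frozen=True)
class ProximityRecord:
    """One scored (source, target) pair: the per-pair output row."""

    source: str
    target: str
    best_distance: float
    z: float
    net_sign: int | str  # +1, -1, 0, or "mixed" when tied-best paths disagree
    significant: bool
    n_paths: int


@dataclass
class ProximityResult(Sequence):
    """Sequence of :class:`ProximityRecord` plus a QC list of targets whose
    distance distribution was degenerate (fewer than 2 paths or zero spread)."""

    records: list[ProximityRecord] = field(default_factory=list)
    degenerate_targets: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


def edge_cost(edge: CausalEdge, cost_model: str = "one_minus_score") -> float:
    """Cost of traversing an edge; strictly decreasing in its trust score."""
    if cost_model == "one_minus_score":
        return 1.0 - edge.score
    if cost_model == "neg_log_score":
        return -math.log(edge.score)
    raise ConfigurationError(f"unknown cost_model {cost_model!r}")


def path_sign(path: CausalPath | Iterable[CausalEdge]) -> int:
    """Net regulatory sign: product of edge effects, 0 if any effect is 0."""
    edges = path.edges if isinstance(path, CausalPath) else tuple(path)
    sign = 1
    for e in edges:
        if e.effect == 0:
            return 0
        sign *= e.effect
    return sign


def _make_path(edges: tuple[CausalEdge, ...], cost_model: str) -> CausalPath:
    return CausalPath(
        edges=edges,
        source=edges[0].source,
        target=edges[-1].target,
        n_steps=len(edges),
        distance=sum(edge_cost(e, cost_model) for e in edges),
        net_sign=path_sign(edges),
    )


def _sort_paths(paths: list[CausalPath]) -> list[CausalPath]:
    return sorted(paths, key=lambda p: (p.distance, p.n_steps, p.nodes))


def enumerate_paths(
    graph: CausalGraph,
    source: str,
    target: str,
    config: ProxConfig = ProxConfig(),
) -> list[CausalPath]:
    """All simple directed paths source -> target with at most ``max_steps`` edges.

    Ordered by ascending distance, ties broken by fewer steps then by the
    lexicographic node sequence.
    """
    for node in (source, target):
        if node not in graph:
            raise KeyError(f"node {node!r} not in graph")
    out: list[CausalPath] = []
    stack: tuple[CausalEdge, ...] = ()
    visited = {source}

    def dfs(node: str, depth: int) -> None:
        nonlocal stack
        for e in graph.successors(node):
            if not config.allow_zero_sign_edges and e.effect == 0:
                continue
            if e.target == target:
                out.append(_make_path(stack + (e,), config.cost_model))
            if depth + 1 < config.max_steps and e.target not in visited and e.target != target:
                visited.add(e.target)
                stack = stack + (e,)
                dfs(e.target, depth + 1)
                stack = stack[:-1]
                visited.discard(e.target)

    dfs(source, 0)
    return _sort_paths(out)


def _paths_to_target(
    graph: CausalGraph, target: str, config: ProxConfig
) -> list[CausalPath]:
    """All simple paths of length <= max_steps ending at ``target`` whose head
    node has an eligible source type.  Reverse DFS over predecessors."""
    allowed = set(config.source_types)
    out: list[CausalPath] = []
    visited = {target}

    def dfs(node: str, suffix: tuple[CausalEdge, ...]) -> None:
        for e in graph.predecessors(node):
            if not config.allow_zero_sign_edges and e.effect == 0:
                continue
            if e.source in visited:
                continue
            edges = (e,) + suffix
            head = graph.entities[e.source]
            if head.entity_type in allowed:
                out.append(_make_path(edges, config.cost_model))
            if len(edges) < config.max_steps:
                visited.add(e.source)
                dfs(e.source, edges)
                visited.discard(e.source)

    dfs(target, ())
    return _sort_paths(out)


def distance_distribution(
    graph: CausalGraph, target: str, config: ProxConfig = ProxConfig()
) -> list[tuple[str, float]]:
    """One (source, distance) entry per enumerated path into ``target``."""
    if target not in graph:
        raise KeyError(f"node {target!r} not in graph")
    return [(p.source, p.distance) for p in _paths_to_target(graph, target, config)]


def proximity_scores(
    graph: CausalGraph,
    targets: Iterable[str],
    config: ProxConfig = ProxConfig(),
) -> ProximityResult:
    """Score every eligible source against each target.

    Per (source, target): ``z = (best_distance - mean(D_t)) / sd(D_t)`` with
    sample (ddof=1) standard deviation over the target's pooled path-distance
    distribution ``D_t``; significant iff ``z < z_threshold``.  ``net_sign``
    is the sign of the best path, or ``"mixed"`` when tied-best paths
    disagree.  Targets with fewer than two paths or zero spread are excluded
    from the records and listed in ``degenerate_targets``.
    """
    result = ProximityResult()
    for target in targets:
        if target not in graph:
            raise KeyError(f"node {target!r} not in graph")
        paths = _paths_to_target(graph, target, config)
        dists = np.array([p.distance for p in paths])
        if len(paths) < 2 or float(np.std(dists, ddof=1)) == 0.0:
            result.degenerate_targets.append(target)
            continue
        mean = float(np.mean(dists))
        sd = float(np.std(dists, ddof=1))
        by_source: dict[str, list[CausalPath]] = {}
        for p in paths:
            by_source.setdefault(p.source, []).append(p)
        for source in sorted(by_source):
            sp = by_source[source]  # already globally sorted; slices keep order
            best = sp[0]
            tied_signs = {p.net_sign for p in sp if p.distance == best.distance}
            net_sign: int | str = best.net_sign if len(tied_signs) == 1 else "mixed"
            z = (best.distance - mean) / sd
            result.records.append(
                ProximityRecord(
                    source=source,
                    target=target,
                    best_distance=best.distance,
                    z=z,
                    net_sign=net_sign,
                    significant=z < config.z_threshold,
                    n_paths=len(sp),
                )
            )
    return result


def significant_subnetwork(
    graph: CausalGraph, records: Iterable[ProximityRecord]
) -> CausalGraph:
    """Graph induced by the significant (source, target) pairs' best paths."""
    from causalprox.graph_model import induced_subgraph

    keep: set[str] = set()
    for r in records:
        if r.significant:
            keep.add(r.source)
            keep.add(r.target)
    return induced_subgraph(graph, keep)
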