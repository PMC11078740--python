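"""Synthetic causal networks with planted ground truth.

Generates directed multipartite graphs emulating a curated causal
interactome: a protein background wired at a stated density with categorical
trust scores, phenotype nodes acting as terminal sinks, pathway membership
labels, and three kinds of planted structure with known ground truth:

* a *proximal module* -- proteins wired to a designated phenotype through
  short high-trust paths (recoverable by proximity scoring);
* a *dense module* -- a protein set with internal edge density far above
  background (recoverable by the connectivity null test);
* *satellite regulators* -- non-member proteins attached to a pathway by a
  single high-trust edge (recoverable by proximity-extended enrichment).

Given the same spec and seed the generator is byte-identical, so emitted
networks double as parser fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from causalprox.graph_model import CausalEdge, CausalGraph, Entity

#: the discrete trust-score vocabulary: curation tiers from 0.1 to 1.0
SCORE_LEVELS = tuple(round(0.1 * i, 1) for i in range(1, 11))

#: default categorical weights over SCORE_LEVELS: curated trust concentrates
#: at mid-range confidence, with top-trust edges rare
SCORE_WEIGHTS = (0.05, 0.10, 0.15, 0.20, 0.20, 0.15, 0.08, 0.04, 0.02, 0.01)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic causal network.

    Defaults describe a mid-size benchmark: 500 background proteins wired at
    density 0.008 (mean in/out degree ~4, as in a sparse curated
    interactome), 5 phenotype sinks, 3 labeled pathways of 15 members, a
    10-protein proximal module planted one score-0.9 step from the first
    phenotype, a 10-protein dense module at internal density 0.5, and 8
    satellite regulators per pathway.  Trust scores are drawn from the
    discrete levels 0.1..1.0 with mid-range-peaked weights (top-trust edges
    rare), matching how curated confidence is distributed in practice;
    ``score_weights=None`` gives the uniform categorical.
    """

    n_proteins: int = 500
    n_phenotypes: int = 5
    n_pathways: int = 3
    background_edge_density: float = 0.008
    score_distribution: tuple[float, ...] = SCORE_LEVELS
    score_weights: tuple[float, ...] | None = SCORE_WEIGHTS
    planted_module_size: int = 10
    planted_path_length: int = 1
    planted_edge_score: float = 0.9
    sign_mix: float = 0.3
    seed: int = 0
    pathway_size: int = 15
    n_satellites: int = 8
    dense_internal_density: float = 0.5
    plant: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.background_edge_density < 1.0):
            raise ValueError("background_edge_density must lie in (0, 1)")
        if not (0.1 <= self.planted_edge_score <= 1.0):
            raise ValueError("planted_edge_score must lie in [0.1, 1]")
        if not (0.0 <= self.sign_mix <= 1.0):
            raise ValueError("sign_mix must lie in [0, 1]")
        if self.score_weights is not None:
            if len(self.score_weights) != len(self.score_distribution):
                raise ValueError("score_weights must match score_distribution")
            if abs(sum(self.score_weights) - 1.0) > 1e-9:
                raise ValueError("score_weights must sum to 1")
        for name in ("n_proteins", "n_phenotypes", "n_pathways",
                     "planted_module_size", "planted_path_length",
                     "pathway_size", "n_satellites"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        reserved = (
            self.planted_module_size * max(1, self.planted_path_length)
            + self.planted_module_size
            + self.n_pathways * (self.pathway_size + self.n_satellites)
        )
        if reserved > self.n_proteins:
            raise ValueError(
                f"spec infeasible: planted structures need {reserved} proteins "
                f"but only {self.n_proteins} available"
            )


@dataclass
class GroundTruth:
    """What was planted, for verification against analysis output."""

    planted_proximal: dict[str, set[str]] = field(default_factory=dict)
    planted_dense_module: set[str] = field(default_factory=set)
    pathway_memberships: dict[str, set[str]] = field(default_factory=dict)
    satellite_regulators: dict[str, set[str]] = field(default_factory=dict)
    relay_nodes: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        def enc(x):
            if isinstance(x, set):
                return sorted(x)
            if isinstance(x, dict):
                return {k: enc(v) for k, v in x.items()}
            return x

        return json.dumps(
            {
                "planted_proximal": enc(self.planted_proximal),
                "planted_dense_module": enc(self.planted_dense_module),
                "pathway_memberships": enc(self.pathway_memberships),
                "satellite_regulators": enc(self.satellite_regulators),
                "relay_nodes": enc(self.relay_nodes),
            },
            indent=2,
            sort_keys=True,
        )


def null_spec(spec: SyntheticSpec) -> SyntheticSpec:
    """Same spec with all planting disabled: pure background, for calibration."""
    return replace(spec, plant=False)


def _draw_score(
    rng: np.random.Generator,
    levels: Sequence[float],
    weights: Sequence[float] | None = None,
) -> float:
    if weights is None:
        return float(levels[rng.integers(0, len(levels))])
    return float(levels[rng.choice(len(levels), p=weights)])


def _draw_sign(rng: np.random.Generator, sign_mix: float) -> int:
    return -1 if rng.random() < sign_mix else 1


def generate(spec: SyntheticSpec) -> tuple[CausalGraph, GroundTruth]:
    """Generate (graph, ground truth) from a spec, deterministically per seed."""
    rng = np.random.default_rng(spec.seed)
    graph = CausalGraph()
    truth = GroundTruth()

    proteins = [f"P{i:04d}" for i in range(spec.n_proteins)]
    phenotypes = [f"PHEN_{j}" for j in range(spec.n_phenotypes)]
    for p in proteins:
        graph.add_entity(Entity(id=p, name=p, entity_type="protein"))
    for ph in phenotypes:
        graph.add_entity(Entity(id=ph, name=ph, entity_type="phenotype"))

    # carve disjoint special sets off the front of the protein list
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        block = proteins[cursor : cursor + n]
        cursor += n
        return block

    if spec.plant:
        proximal = take(spec.planted_module_size)
        dense = take(spec.planted_module_size)
        truth.planted_proximal[phenotypes[0]] = set(proximal)
        truth.planted_dense_module = set(dense)
    pathway_members: dict[str, list[str]] = {}
    satellites: dict[str, list[str]] = {}
    for j in range(spec.n_pathways):
        name = f"PW{j}"
        pathway_members[name] = take(spec.pathway_size)
        truth.pathway_memberships[name] = set(pathway_members[name])
        if spec.plant:
            satellites[name] = take(spec.n_satellites)
            truth.satellite_regulators[name] = set(satellites[name])

    # background: protein -> protein and protein -> phenotype at stated density
    levels = spec.score_distribution
    n = spec.n_proteins
    mask = rng.random((n, n)) < spec.background_edge_density
    np.fill_diagonal(mask, False)
    srcs, tgts = np.nonzero(mask)
    for i, j in zip(srcs.tolist(), tgts.tolist()):
        graph.add_edge(
            CausalEdge(
                source=proteins[i],
                target=proteins[j],
                effect=_draw_sign(rng, spec.sign_mix),
                score=_draw_score(rng, levels, spec.score_weights),
            )
        )
    ph_mask = rng.random((n, spec.n_phenotypes)) < spec.background_edge_density
    srcs, tgts = np.nonzero(ph_mask)
    for i, j in zip(srcs.tolist(), tgts.tolist()):
        graph.add_edge(
            CausalEdge(
                source=proteins[i],
                target=phenotypes[j],
                effect=_draw_sign(rng, spec.sign_mix),
                score=_draw_score(rng, levels, spec.score_weights),
            )
        )

    if spec.plant:
        # proximal module: each planted protein reaches phenotype 0 through a
        # path of planted_path_length edges, all at planted_edge_score
        target = phenotypes[0]
        for idx, p in enumerate(sorted(truth.planted_proximal[target])):
            chain = [p]
            for step in range(spec.planted_path_length - 1):
                relay = f"RELAY_{idx}_{step}"
                graph.add_entity(Entity(id=relay, name=relay, entity_type="protein"))
                truth.relay_nodes.add(relay)
                chain.append(relay)
            chain.append(target)
            for a, b in zip(chain[:-1], chain[1:]):
                graph.add_edge(
                    CausalEdge(
                        source=a, target=b, effect=1,
                        score=spec.planted_edge_score,
                    )
                )

        # dense module: internal wiring far above background
        dense_sorted = sorted(truth.planted_dense_module)
        for a in dense_sorted:
            for b in dense_sorted:
                if a != b and rng.random() < spec.dense_internal_density:
                    graph.add_edge(
                        CausalEdge(
                            source=a, target=b,
                            effect=_draw_sign(rng, spec.sign_mix),
                            score=_draw_score(rng, levels, spec.score_weights),
                        )
                    )

        # satellite regulators: one high-trust edge into the pathway's first member
        for name in sorted(satellites):
            hub = pathway_members[name][0]
            for s in satellites[name]:
                graph.add_edge(
                    CausalEdge(
                        source=s, target=hub, effect=1,
                        score=spec.planted_edge_score,
                    )
                )

        # light internal pathway wiring: members form a causal chain
        for name in sorted(pathway_members):
            members = pathway_members[name]
            for a, b in zip(members[:-1], members[1:]):
                graph.add_edge(
                    CausalEdge(
                        source=a, target=b, effect=_draw_sign(rng, spec.sign_mix),
                        score=_draw_score(rng, levels, spec.score_weights),
                    )
                )

    return graph, truth
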