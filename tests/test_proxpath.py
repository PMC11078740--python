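import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from causalprox.graph_model import CausalEdge
from causalprox.proxpath import (
    ConfigurationError,
    ProxConfig,
    distance_distribution,
    edge_cost,
    enumerate_paths,
    path_sign,
    proximity_scores,
)
from conftest import make_graph, random_graph


def edge(score=0.5, effect=1, src="A", tgt="B"):
    return CausalEdge(source=src, target=tgt, effect=effect, score=score)


class TestEdgeCost:
    @pytest.mark.parametrize(
        "score,model,expected",
        [
            (1.0, "one_minus_score", 0.0),
            (0.5, "one_minus_score", 0.5),
            (0.1, "neg_log_score", -math.log(0.1)),
        ],
    )
    def test_closed_forms(self, score, model, expected):
        assert edge_cost(edge(score), model) == pytest.approx(expected)

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigurationError):
            edge_cost(edge(), "resistance")

    @given(st.floats(min_value=0.1, max_value=1.0),
           st.floats(min_value=0.1, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_score(self, s1, s2):
        for model in ("one_minus_score", "neg_log_score"):
            c1, c2 = edge_cost(edge(s1), model), edge_cost(edge(s2), model)
            if s1 < s2:
                assert c1 > c2
            elif s1 == s2:
                assert c1 == c2


class TestPathSign:
    @pytest.mark.parametrize(
        "effects,expected",
        [((1, 1), 1), ((-1, -1), 1), ((-1, 0, 1), 0), ((1, -1), -1), ((-1,), -1)],
    )
    def test_sign_algebra(self, effects, expected):
        edges = [edge(effect=e) for e in effects]
        assert path_sign(edges) == expected

    @given(st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=6),
           st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_concatenation_is_product(self, e1, e2):
        s1 = path_sign([edge(effect=e) for e in e1])
        s2 = path_sign([edge(effect=e) for e in e2])
        assert path_sign([edge(effect=e) for e in e1 + e2]) == s1 * s2


def dfs_oracle(graph, source, target, max_steps, cost_model="one_minus_score"):
    """Exhaustive simple-path enumeration via networkx, independent of the
    package's own traversal."""
    nxg = graph.to_networkx()
    out = []
    for epath in nx.all_simple_edge_paths(nxg, source, target, cutoff=max_steps):
        attrs = [nxg.edges[u, v, k] for u, v, k in epath]
        dist = sum(1 - a["score"] if cost_model == "one_minus_score"
                   else -math.log(a["score"]) for a in attrs)
        effects = [a["effect"] for a in attrs]
        sign = 0 if 0 in effects else int(np.prod(effects))
        nodes = tuple([epath[0][0]] + [v for _, v, _ in epath])
        out.append((nodes, round(dist, 12), sign))
    return sorted(out)


class TestEnumeratePaths:
    def test_single_edge(self):
        g = make_graph([("A", "B", 1, 0.5)])
        paths = enumerate_paths(g, "A", "B")
        assert len(paths) == 1 and paths[0].n_steps == 1

    def test_step_bound_enforced(self):
        g = make_graph([("A", "B", 1, 0.5), ("B", "C", 1, 0.5),
                        ("C", "D", 1, 0.5), ("D", "E", 1, 0.5)])
        assert enumerate_paths(g, "A", "E", ProxConfig(max_steps=3)) == []
        assert len(enumerate_paths(g, "A", "E", ProxConfig(max_steps=4))) == 1

    def test_missing_node_raises(self):
        g = make_graph([("A", "B", 1, 0.5)])
        with pytest.raises(KeyError):
            enumerate_paths(g, "A", "Z")

    def test_ordering_distance_then_steps_then_lex(self):
        g = make_graph([
            ("A", "B", 1, 0.9), ("B", "C", 1, 0.9),   # dist 0.2, 2 steps
            ("A", "C", 1, 0.8),                        # dist 0.2, 1 step
            ("A", "D", 1, 0.9), ("D", "C", 1, 0.5),   # dist 0.6
        ])
        paths = enumerate_paths(g, "A", "C")
        assert [p.nodes for p in paths] == [("A", "C"), ("A", "B", "C"),
                                            ("A", "D", "C")]

    @pytest.mark.parametrize("max_steps", [2, 3, 4])
    def test_matches_exhaustive_dfs_oracle(self, rng, max_steps):
        for _ in range(15):
            n = int(rng.integers(6, 26))
            g = random_graph(rng, n, int(rng.integers(n, 4 * n)))
            nodes = sorted(g.entities)
            pairs = [(a, b) for a in nodes[:8] for b in nodes[-8:] if a != b]
            cfg = ProxConfig(max_steps=max_steps)
            for s, t in pairs[:20]:
                got = sorted(
                    (p.nodes, round(p.distance, 12), p.net_sign)
                    for p in enumerate_paths(g, s, t, cfg)
                )
                assert got == dfs_oracle(g, s, t, max_steps)


class TestDistanceDistribution:
    def test_star_graph_arithmetic(self):
        g = make_graph(
            [("A", "P", 1, 0.5), ("B", "P", 1, 0.7), ("C", "P", 1, 0.9)],
            entity_types={"P": "phenotype"},
        )
        dd = distance_distribution(g, "P")
        assert sorted(d for _, d in dd) == pytest.approx([0.1, 0.3, 0.5])

    def test_no_incoming_paths_is_empty(self):
        g = make_graph([("A", "B", 1, 0.5)], entity_types={"A": "phenotype"})
        assert distance_distribution(g, "A") == []

    def test_size_matches_oracle_path_count(self, default_net):
        g, _ = default_net
        nxg = g.to_networkx()
        dd = distance_distribution(g, "PHEN_1")
        protein_nodes = [n for n in nxg if nxg.nodes[n]["entity_type"]
                         in ("protein", "complex")]
        n_oracle = sum(
            1
            for src in protein_nodes
            for _ in nx.all_simple_edge_paths(nxg, src, "PHEN_1", cutoff=3)
        )
        assert len(dd) == n_oracle


class TestProximityScores:
    def test_z_from_three_point_distribution(self):
        # equally spaced distances 0.1/0.5/0.9 have sample sd 0.4, so the
        # closest source scores z = (0.1 - 0.5) / 0.4 = -1: not significant
        g = make_graph(
            [("A", "P", 1, 0.9), ("B", "P", 1, 0.5), ("C", "P", 1, 0.1)],
            entity_types={"P": "phenotype"},
        )
        res = proximity_scores(g, ["P"])
        recs = {r.source: r for r in res}
        assert recs["A"].z == pytest.approx((0.1 - 0.5) / 0.4)
        assert not recs["A"].significant

    def test_degenerate_target_flagged(self):
        g = make_graph(
            [("A", "P", 1, 0.5), ("B", "P", 1, 0.5)],
            entity_types={"P": "phenotype"},
        )
        res = proximity_scores(g, ["P"])
        assert res.degenerate_targets == ["P"]
        assert len(res.records) == 0

    def test_planted_module_recovery(self, default_net):
        g, truth = default_net
        res = proximity_scores(g, ["PHEN_0"])
        planted = truth.planted_proximal["PHEN_0"]
        sig = {r.source for r in res if r.significant}
        assert planted <= sig
        decoys = [r for r in res if r.source not in planted]
        rate = sum(r.significant for r in decoys) / len(decoys)
        assert rate < 0.05

    def test_determinism(self, default_net):
        g, _ = default_net
        a = proximity_scores(g, ["PHEN_2"])
        b = proximity_scores(g, ["PHEN_2"])
        assert a.records == b.records

    def test_path_z_distribution_normalized(self, default_net):
        # within each target the z-scores of all enumerated paths must have
        # mean 0 and sample sd 1 by construction of the normalization
        g, _ = default_net
        for target in g.phenotypes:
            dd = np.array([d for _, d in distance_distribution(g, target)])
            if len(dd) < 2 or dd.std(ddof=1) == 0:
                continue
            z = (dd - dd.mean()) / dd.std(ddof=1)
            assert abs(z.mean()) < 1e-9
            assert abs(z.std(ddof=1) - 1) < 1e-9

    def test_monotonicity_in_edge_score(self):
        # raising the score of the best path's edge cannot increase best_distance
        g1 = make_graph(
            [("A", "P", 1, 0.5), ("B", "P", 1, 0.3), ("C", "P", 1, 0.8)],
            entity_types={"P": "phenotype"},
        )
        g2 = make_graph(
            [("A", "P", 1, 0.7), ("B", "P", 1, 0.3), ("C", "P", 1, 0.8)],
            entity_types={"P": "phenotype"},
        )
        d1 = {r.source: r.best_distance for r in proximity_scores(g1, ["P"])}
        d2 = {r.source: r.best_distance for r in proximity_scores(g2, ["P"])}
        assert d2["A"] <= d1["A"]

    def test_mixed_sign_on_tied_best_paths(self):
        g = make_graph(
            [("A", "M", 1, 0.8), ("M", "P", 1, 0.8),
             ("A", "N", 1, 0.8), ("N", "P", -1, 0.8),
             ("B", "P", 1, 0.3)],
            entity_types={"P": "phenotype"},
        )
        recs = {r.source: r for r in proximity_scores(g, ["P"])}
        assert recs["A"].net_sign == "mixed"
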