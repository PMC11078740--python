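import numpy as np
import pytest

from causalprox.graph_model import CausalEdge, CausalGraph, Entity
from causalprox.synthetic import SyntheticSpec, generate


def make_graph(edges, entity_types=None):
    """Build a CausalGraph from (source, target, effect, score) tuples."""
    g = CausalGraph()
    entity_types = entity_types or {}
    nodes = {n for e in edges for n in (e[0], e[1])}
    for n in sorted(nodes):
        g.add_entity(Entity(id=n, name=n, entity_type=entity_types.get(n, "protein")))
    for src, tgt, eff, score in edges:
        g.add_edge(CausalEdge(source=src, target=tgt, effect=eff, score=score))
    return g


def random_graph(rng, n_nodes, n_edges, phenotypes=0):
    """Random directed graph with discrete scores, optionally with sink phenotypes."""
    g = CausalGraph()
    names = [f"N{i}" for i in range(n_nodes)]
    types = {}
    for j in range(phenotypes):
        types[names[-1 - j]] = "phenotype"
    for n in names:
        g.add_entity(Entity(id=n, name=n, entity_type=types.get(n, "protein")))
    added = 0
    attempts = 0
    while added < n_edges and attempts < 20 * n_edges:
        attempts += 1
        i, j = rng.integers(0, n_nodes, size=2)
        if i == j:
            continue
        src, tgt = names[i], names[j]
        if types.get(src) == "phenotype":
            continue
        score = float(rng.integers(1, 11)) / 10
        effect = int(rng.choice([-1, 0, 1]))
        if g.add_edge(CausalEdge(source=src, target=tgt, effect=effect, score=score)):
            added += 1
    return g


@pytest.fixture(scope="session")
def default_net():
    """One default-spec synthetic network with ground truth, shared per session."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
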