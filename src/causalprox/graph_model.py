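"""Signed, directed, trust-weighted causal interaction graphs and their formats.

The central container is :class:`CausalGraph`, a directed multigraph over typed
biological entities (proteins, complexes, small molecules, phenotypes, ...)
whose edges carry a regulatory sign (+1 up-regulates, -1 down-regulates, 0
unknown/complex) and a curated trust score in [0.1, 1.0].  Readers and writers
cover the SIGNOR full-download TSV dialect, generic 4-column edge lists, SIF,
and GMT gene-set collections.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

ENTITY_TYPES = frozenset(
    {
        "protein",
        "complex",
        "smallmolecule",
        "phenotype",
        "stimulus",
        "fusion_protein",
        "proteinfamily",
        "mirna",
        "other",
    }
)

#: SIGNOR-style TYPE column values mapped onto the closed entity vocabulary.
_TYPE_ALIASES = {
    "protein": "protein",
    "complex": "complex",
    "smallmolecule": "smallmolecule",
    "chemical": "smallmolecule",
    "phenotype": "phenotype",
    "stimulus": "stimulus",
    "fusion protein": "fusion_protein",
    "fusion_protein": "fusion_protein",
    "proteinfamily": "proteinfamily",
    "protein family": "proteinfamily",
    "mirna": "mirna",
    "antibody": "other",
}

#: Default SIGNOR full-download column names; override via the ``dialect`` map.
SIGNOR_DIALECT = {
    "entity_a": "ENTITYA",
    "type_a": "TYPEA",
    "id_a": "IDA",
    "entity_b": "ENTITYB",
    "type_b": "TYPEB",
    "id_b": "IDB",
    "effect": "EFFECT",
    "mechanism": "MECHANISM",
    "pmid": "PMID",
    "score": "SCORE",
}

_SIGN_TOKENS = {
    "+": 1,
    "-": -1,
    "0": 0,
    "up": 1,
    "down": -1,
    "unknown": 0,
}

_SIF_RELATION = {1: "up-regulates", -1: "down-regulates", 0: "unknown"}
_SIF_RELATION_INV = {v: k for k, v in _SIF_RELATION.items()}


class FormatError(ValueError):
    """Malformed input file (missing column, unparsable field)."""


class ValidationError(ValueError):
    """Input violates a graph invariant (score range, sign vocabulary)."""


def map_effect(token: str) -> int:
    """Map a SIGNOR EFFECT label onto a regulatory sign.

    Any label starting with ``up-regulates`` maps to +1, ``down-regulates``
    to -1, and everything else (``form complex``, ``unknown``, ...) to 0.
    """
    t = token.strip().lower()
    if t.startswith("up-regulates"):
        return 1
    if t.startswith("down-regulates"):
        return -1
    return 0


@dataclass(frozen=True)
class Entity:
    """A node of the causal interactome: a typed biological entity."""

    id: str
    name: str = ""
    entity_type: str = "protein"
    database: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("entity id must be non-empty")
        if self.entity_type not in ENTITY_TYPES:
            raise ValidationError(
                f"unknown entity_type {self.entity_type!r}; "
                f"expected one of {sorted(ENTITY_TYPES)}"
            )


@dataclass(frozen=True)
class CausalEdge:
    """A signed, trust-scored causal interaction A -> B."""

    source: str
    target: str
    effect: int
    score: float
    mechanism: str = ""
    pmids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.effect not in (-1, 0, 1):
            raise ValidationError(f"effect must be -1, 0 or +1, got {self.effect}")
        if not (0.1 <= self.score <= 1.0):
            raise ValidationError(
                f"score must lie in [0.1, 1.0], got {self.score}"
            )

    @property
    def key(self) -> tuple[str, str, int, str]:
        """Identity for de-duplication: parallel edges must differ in effect or mechanism."""
        return (self.source, self.target, self.effect, self.mechanism)


class CausalGraph:
    """Directed multigraph of typed entities with signed, scored edges.

    Maintains an id -> :class:`Entity` map and an edge list, plus successor /
    predecessor indices for traversal.  Parallel edges between the same
    ordered pair are retained when they differ in effect or mechanism
    (conflicting literature evidence is kept, not collapsed).
    """

    def __init__(self) -> None:
        self.entities: dict[str, Entity] = {}
        self.edges: list[CausalEdge] = []
        self._succ: dict[str, list[CausalEdge]] = {}
        self._pred: dict[str, list[CausalEdge]] = {}
        self._edge_keys: set[tuple[str, str, int, str]] = set()

    # -- construction -----------------------------------------------------
    def add_entity(self, entity: Entity) -> None:
        existing = self.entities.get(entity.id)
        if existing is None:
            self.entities[entity.id] = entity
            self._succ.setdefault(entity.id, [])
            self._pred.setdefault(entity.id, [])
        elif existing.entity_type == "other" and entity.entity_type != "other":
            # a later row may know the real type
            self.entities[entity.id] = entity

    def add_edge(self, edge: CausalEdge, dedupe: bool = True) -> bool:
        """Add an edge; returns False if a duplicate was dropped."""
        for nid in (edge.source, edge.target):
            if nid not in self.entities:
                self.add_entity(Entity(id=nid, name=nid))
        if dedupe and edge.key in self._edge_keys:
            return False
        self.edges.append(edge)
        self._edge_keys.add(edge.key)
        self._succ[edge.source].append(edge)
        self._pred[edge.target].append(edge)
        return True

    # -- views ------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.entities)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def successors(self, node: str) -> list[CausalEdge]:
        return self._succ.get(node, [])

    def predecessors(self, node: str) -> list[CausalEdge]:
        return self._pred.get(node, [])

    def nodes_of_type(self, *types: str) -> list[str]:
        return sorted(
            nid for nid, e in self.entities.items() if e.entity_type in types
        )

    @property
    def proteins(self) -> list[str]:
        return self.nodes_of_type("protein")

    @property
    def phenotypes(self) -> list[str]:
        return self.nodes_of_type("phenotype")

    def __contains__(self, node: str) -> bool:
        return node in self.entities

    def copy(self) -> "CausalGraph":
        g = CausalGraph()
        for e in self.entities.values():
            g.add_entity(e)
        for edge in self.edges:
            g.add_edge(edge, dedupe=False)
        g._edge_keys = set(self._edge_keys)
        return g

    def to_networkx(self) -> nx.MultiDiGraph:
        """Export to a networkx MultiDiGraph (edge attrs: effect, score, mechanism)."""
        g = nx.MultiDiGraph()
        for nid, ent in self.entities.items():
            g.add_node(nid, name=ent.name, entity_type=ent.entity_type)
        for e in self.edges:
            g.add_edge(
                e.source, e.target, effect=e.effect, score=e.score,
                mechanism=e.mechanism,
            )
        return g

    def __repr__(self) -> str:  # pragma: no cover
        return f"CausalGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class GeneSetCollection:
    """Named gene sets (pathway memberships, candidate lists) as read from GMT."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        clean = {m for m in members if m}
        self.sets[name] = clean
        self.descriptions[name] = description

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


# -- readers ---------------------------------------------------------------

def _as_lines(stream) -> Iterable[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def parse_signor_tsv(
    stream,
    dialect: Mapping[str, str] | None = None,
    strict: bool = True,
) -> CausalGraph:
    """Read a SIGNOR-style full-download TSV into a :class:`CausalGraph`.

    Parameters
    ----------
    stream
        Text lines or a string containing the file; a header row is required.
    dialect
        Column-name overrides for the keys of :data:`SIGNOR_DIALECT`.
    strict
        If True, a SCORE outside [0.1, 1] raises :class:`ValidationError`
        citing the row number; if False, the row is skipped and tallied.
    """
    cols = dict(SIGNOR_DIALECT)
    if dialect:
        cols.update(dialect)
    lines = iter(_as_lines(stream))
    try:
        header = next(lines).rstrip("\n").split("\t")
    except StopIteration:
        raise FormatError("empty input: header row required") from None
    idx = {name: i for i, name in enumerate(header)}
    mandatory = ["entity_a", "entity_b", "effect", "score"]
    for key in mandatory:
        if cols[key] not in idx:
            raise FormatError(f"missing mandatory column {cols[key]!r}")

    def get(row: list[str], key: str, default: str = "") -> str:
        col = cols[key]
        i = idx.get(col)
        if i is None or i >= len(row):
            return default
        return row[i]

    graph = CausalGraph()
    skipped = 0
    unmapped_types = 0
    for rownum, raw in enumerate(lines, start=2):
        if not raw.strip() or raw.startswith("#"):
            continue
        row = raw.rstrip("\n").split("\t")
        try:
            score = float(get(row, "score"))
        except ValueError:
            raise FormatError(
                f"row {rownum}: SCORE not parseable as a real number"
            ) from None
        if not (0.1 <= score <= 1.0):
            if strict:
                raise ValidationError(
                    f"row {rownum}: SCORE {score} outside [0.1, 1.0]"
                )
            skipped += 1
            continue
        for side, type_key, id_key in (
            ("entity_a", "type_a", "id_a"),
            ("entity_b", "type_b", "id_b"),
        ):
            name = get(row, side)
            nid = get(row, id_key) or name
            raw_type = get(row, type_key, "protein").strip().lower()
            etype = _TYPE_ALIASES.get(raw_type)
            if etype is None:
                etype = "other"
                unmapped_types += 1
            graph.add_entity(Entity(id=nid, name=name, entity_type=etype))
        src = get(row, "id_a") or get(row, "entity_a")
        tgt = get(row, "id_b") or get(row, "entity_b")
        pmid = get(row, "pmid")
        graph.add_edge(
            CausalEdge(
                source=src,
                target=tgt,
                effect=map_effect(get(row, "effect")),
                score=score,
                mechanism=get(row, "mechanism"),
                pmids=tuple(p for p in pmid.split(";") if p),
            )
        )
    if skipped:
        logger.warning("skipped %d rows with out-of-range scores", skipped)
    if unmapped_types:
        logger.warning("%d entity type labels routed to 'other'", unmapped_types)
    return graph


def parse_edge_list(stream) -> CausalGraph:
    """Read a generic >=4-column edge list: source, target, sign, score.

    Sign tokens: ``+ - 0 up down unknown``.  Entity types default to protein.
    Self-loops are accepted and counted in a warning.
    """
    graph = CausalGraph()
    self_loops = 0
    for rownum, raw in enumerate(_as_lines(stream), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split()
        if len(parts) < 4:
            raise FormatError(
                f"row {rownum}: expected >= 4 whitespace-separated columns"
            )
        src, tgt, sign_tok, score_tok = parts[0], parts[1], parts[2], parts[3]
        if sign_tok.lower() not in _SIGN_TOKENS:
            raise FormatError(
                f"row {rownum}: sign token {sign_tok!r} not in "
                f"{sorted(_SIGN_TOKENS)}"
            )
        try:
            score = float(score_tok)
        except ValueError:
            raise FormatError(
                f"row {rownum}: score {score_tok!r} is not numeric"
            ) from None
        if src == tgt:
            self_loops += 1
        graph.add_edge(
            CausalEdge(
                source=src,
                target=tgt,
                effect=_SIGN_TOKENS[sign_tok.lower()],
                score=score,
            )
        )
    if self_loops:
        logger.warning("edge list contains %d self-loop(s)", self_loops)
    return graph


def parse_sif(stream) -> CausalGraph:
    """Read SIF lines ``source <relation> target`` (scores default to 1.0)."""
    graph = CausalGraph()
    for rownum, raw in enumerate(_as_lines(stream), start=1):
        if not raw.strip():
            continue
        parts = raw.split("\t") if "\t" in raw else raw.split()
        if len(parts) < 3:
            raise FormatError(f"row {rownum}: SIF needs source, relation, target")
        src, rel, tgt = parts[0].strip(), parts[1].strip(), parts[2].strip()
        effect = _SIF_RELATION_INV.get(rel, 0)
        score = float(parts[3]) if len(parts) > 3 else 1.0
        graph.add_edge(CausalEdge(source=src, target=tgt, effect=effect, score=score))
    return graph


def parse_gmt(stream) -> GeneSetCollection:
    """Read a GMT file: tab-separated set name, description, members."""
    coll = GeneSetCollection()
    for raw in _as_lines(stream):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError("GMT lines need at least name and description")
        coll.add(parts[0], parts[2:], description=parts[1])
    return coll


def read_gene_list(stream) -> list[str]:
    """Read one gene id per line, ignoring blanks and ``#`` comments."""
    out: list[str] = []
    seen: set[str] = set()
    for raw in _as_lines(stream):
        token = raw.strip()
        if not token or token.startswith("#"):
            continue
        if token not in seen:
            seen.add(token)
            out.append(token)
    return out


# -- writers ---------------------------------------------------------------

def write_sif(graph: CausalGraph) -> str:
    """Serialize edges as SIF with a 4th score column (parse_sif round-trips)."""
    lines = [
        f"{e.source}\t{_SIF_RELATION[e.effect]}\t{e.target}\t{e.score:g}"
        for e in graph.edges
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def write_edge_list(graph: CausalGraph) -> str:
    sign = {1: "+", -1: "-", 0: "0"}
    lines = [
        f"{e.source}\t{e.target}\t{sign[e.effect]}\t{e.score:g}"
        for e in graph.edges
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def write_signor_tsv(graph: CausalGraph) -> str:
    """Serialize a graph in the SIGNOR TSV dialect (parse_signor_tsv round-trips)."""
    effect_label = {1: "up-regulates", -1: "down-regulates", 0: "unknown"}
    cols = SIGNOR_DIALECT
    header = "\t".join(
        cols[k]
        for k in (
            "entity_a", "type_a", "id_a", "entity_b", "type_b", "id_b",
            "effect", "mechanism", "pmid", "score",
        )
    )
    lines = [header]
    for e in graph.edges:
        a = graph.entities[e.source]
        b = graph.entities[e.target]
        lines.append(
            "\t".join(
                [
                    a.name or a.id, a.entity_type, a.id,
                    b.name or b.id, b.entity_type, b.id,
                    effect_label[e.effect], e.mechanism, ";".join(e.pmids),
                    f"{e.score:g}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_gmt(collection: GeneSetCollection) -> str:
    lines = [
        "\t".join(
            [name, collection.descriptions.get(name, "")]
            + sorted(collection.sets[name])
        )
        for name in collection.sets
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def write_results_table(records: Sequence, sep: str = "\t") -> str:
    """Serialize a sequence of dataclass records or dicts as delimited text."""
    if not records:
        return ""
    rows = []
    for r in records:
        if hasattr(r, "__dataclass_fields__"):
            rows.append({k: getattr(r, k) for k in r.__dataclass_fields__})
        else:
            rows.append(dict(r))
    df = pd.DataFrame(rows)
    return df.to_csv(sep=sep, index=False)


# -- graph operations ------------------------------------------------------

def induced_subgraph(graph: CausalGraph, node_ids: Iterable[str]) -> CausalGraph:
    """Restrict the graph to ``node_ids`` and edges with both endpoints inside.

    Unknown ids are ignored with a warning.
    """
    wanted = set(node_ids)
    unknown = wanted - set(graph.entities)
    if unknown:
        logger.warning("ignoring %d unknown node ids", len(unknown))
        wanted -= unknown
    sub = CausalGraph()
    for nid in wanted:
        sub.add_entity(graph.entities[nid])
    for e in graph.edges:
        if e.source in wanted and e.target in wanted:
            sub.add_edge(e, dedupe=False)
    return sub
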