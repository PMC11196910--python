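"""Typed heterogeneous knowledge graph: patients, symptoms, syndromes and
curated clinical concepts as nodes, with undirected adjacency for neighbor
queries and directed relation records for serialization.

The graph is the substrate for every similarity score in this package: a
patient's neighbors are the symptom/attribute entities recorded for them
(plus their syndrome node when diagnosed), and two patients are compared
through the entities they share.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


import networkx as nx

#: Closed node-type vocabulary. Covers every concept class the clinical
#: sources name: patient records, symptoms/signs, the five syndrome patterns,
#: diseases, drugs, treatment methods, and demographic/contextual attributes.
ETYPES = frozenset(
    {"patient", "symptom", "syndrome", "disease", "drug", "treatment", "attribute"}
)

FORMATS = ("tsv", "json", "graphml")


class GraphError(ValueError):
    """Raised for invalid graph operations (bad etype, dangling endpoint...)."""


@dataclass
class Entity:
    """A typed node. ``id`` is an ASCII-safe key; ``label`` is the display
    name and may be non-ASCII (the source vocabulary is Chinese)."""

    id: str
    label: str
    etype: str
    aliases: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.etype not in ETYPES:
            raise GraphError(
                f"invalid etype {self.etype!r} for entity {self.id!r}; "
                f"expected one of {sorted(ETYPES)}"
            )


@dataclass
class Relation:
    """A typed edge. ``rtype`` keeps the semantic direction (source -> target)
    for serialization; traversal treats the edge as undirected."""

    source: str
    target: str
    rtype: str
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.weight is not None and self.weight < 0:
            raise GraphError(
                f"negative weight {self.weight} on relation "
                f"{self.source!r}-[{self.rtype}]->{self.target!r}"
            )


class KnowledgeGraph:
    """Entity/relation store with an undirected adjacency index.

    Entities are unique by id; re-upserting merges aliases. Relations are
    unique by (source, target, rtype); re-upserting overwrites the weight.
    """

    def __init__(self) -> None:
        self._entities: dict[str, Entity] = {}
        self._relations: dict[tuple[str, str, str], Relation] = {}
        self._adj = nx.Graph()

    # -- entity / relation maintenance -------------------------------------

    def upsert_entity(self, entity: Entity) -> "KnowledgeGraph":
        existing = self._entities.get(entity.id)
        if existing is None:
            self._entities[entity.id] = Entity(
                entity.id, entity.label, entity.etype, set(entity.aliases)
            )
            self._adj.add_node(entity.id)
        else:
            if existing.etype != entity.etype:
                raise GraphError(
                    f"entity {entity.id!r} re-upserted with etype "
                    f"{entity.etype!r} != existing {existing.etype!r}"
                )
            existing.aliases |= entity.aliases
        return self

    def upsert_relation(self, relation: Relation) -> "KnowledgeGraph":
        for endpoint in (relation.source, relation.target):
            if endpoint not in self._entities:
                raise GraphError(f"relation endpoint {endpoint!r} not in graph")
        key = (relation.source, relation.target, relation.rtype)
        self._relations[key] = Relation(*key, relation.weight)
        self._adj.add_edge(relation.source, relation.target)
        return self

    # -- queries ------------------------------------------------------------

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._entities

    def entity(self, entity_id: str) -> Entity:
        try:
            return self._entities[entity_id]
        except KeyError:
            raise GraphError(f"unknown entity id {entity_id!r}") from None

    @property
    def entities(self) -> list[Entity]:
        return list(self._entities.values())

    @property
    def relations(self) -> list[Relation]:
        return list(self._relations.values())

    @property
    def n_entities(self) -> int:
        return len(self._entities)

    @property
    def n_relations(self) -> int:
        return len(self._relations)

    def entity_ids(self, etype: str | None = None) -> list[str]:
        if etype is None:
            return list(self._entities)
        return [e.id for e in self._entities.values() if e.etype == etype]

    def degree(self, entity_id: str) -> int:
        self.entity(entity_id)
        return self._adj.degree(entity_id)

    def neighbors(self, entity_id: str, etype: str | None = None) -> set[str]:
        """Adjacent entity ids, optionally restricted to one node type."""
        self.entity(entity_id)
        nbrs = set(self._adj.neighbors(entity_id))
        if etype is None:
            return nbrs
        if etype not in ETYPES:
            raise GraphError(f"invalid etype filter {etype!r}")
        return {n for n in nbrs if self._entities[n].etype == etype}

    def common_neighbors(self, a: str, b: str) -> set[str]:
        if a == b:
            raise GraphError(f"common neighbors of {a!r} with itself are undefined")
        return self.neighbors(a) & self.neighbors(b)

    # -- serialization -------------------------------------------------------

    def save(self, path: str | Path, fmt: str = "json") -> None:
        save_graph(self, path, fmt)

    @classmethod
    def load(cls, path: str | Path, fmt: str = "json") -> "KnowledgeGraph":
        return load_graph(path, fmt)


# Thin functional wrappers, mirroring the operation surface.


def upsert_entity(graph: KnowledgeGraph, entity: Entity) -> KnowledgeGraph:
    return graph.upsert_entity(entity)


def upsert_relation(graph: KnowledgeGraph, relation: Relation) -> KnowledgeGraph:
    return graph.upsert_relation(relation)


def neighbors(
    graph: KnowledgeGraph, entity_id: str, etype: str | None = None
) -> set[str]:
    return graph.neighbors(entity_id, etype)


def common_neighbors(graph: KnowledgeGraph, a: str, b: str) -> set[str]:
    return graph.common_neighbors(a, b)


# -- file formats -----------------------------------------------------------

_NODE_HEADER = ["id", "label", "etype", "aliases"]
_EDGE_HEADER = ["source", "target", "rtype", "weight"]


def _check_fmt(fmt: str) -> None:
    if fmt not in FORMATS:
        raise GraphError(f"unknown graph format {fmt!r}; expected one of {FORMATS}")


def _tsv_paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    return base.with_suffix(base.suffix + ".nodes.tsv"), base.with_suffix(
        base.suffix + ".edges.tsv"
    )


def save_graph(graph: KnowledgeGraph, path: str | Path, fmt: str = "json") -> None:
    """Write the graph. ``tsv`` emits a <path>.nodes.tsv / <path>.edges.tsv
    pair; ``json`` a single file; ``graphml`` an export for visualization
    (parallel relations between one node pair collapse to a single edge)."""
    _check_fmt(fmt)
    path = Path(path)
    if fmt == "tsv":
        nodes_path, edges_path = _tsv_paths(path)
        with nodes_path.open("w", encoding="utf-8") as fh:
            fh.write("\t".join(_NODE_HEADER) + "\n")
            for e in graph.entities:
                fh.write(
                    "\t".join([e.id, e.label, e.etype, "|".join(sorted(e.aliases))])
                    + "\n"
                )
        with edges_path.open("w", encoding="utf-8") as fh:
            fh.write("\t".join(_EDGE_HEADER) + "\n")
            for r in graph.relations:
                w = "" if r.weight is None else repr(r.weight)
                fh.write("\t".join([r.source, r.target, r.rtype, w]) + "\n")
    elif fmt == "json":
        doc = {
            "entities": [
                {
                    "id": e.id,
                    "label": e.label,
                    "etype": e.etype,
                    "aliases": sorted(e.aliases),
                }
                for e in graph.entities
            ],
            "relations": [
                {
                    "source": r.source,
                    "target": r.target,
                    "rtype": r.rtype,
                    "weight": r.weight,
                }
                for r in graph.relations
            ],
        }
        path.write_text(
            json.dumps(doc, ensure_ascii=False, indent=1), encoding="utf-8"
        )
    else:  # graphml
        g = nx.Graph()
        for e in graph.entities:
            g.add_node(
                e.id, label=e.label, etype=e.etype, aliases="|".join(sorted(e.aliases))
            )
        for r in graph.relations:
            attrs = {"rtype": r.rtype}
            if r.weight is not None:
                attrs["weight"] = r.weight
            g.add_edge(r.source, r.target, **attrs)
        nx.write_graphml(g, path)


def load_graph(path: str | Path, fmt: str = "json") -> KnowledgeGraph:
    _check_fmt(fmt)
    path = Path(path)
    graph = KnowledgeGraph()
    if fmt == "tsv":
        nodes_path, edges_path = _tsv_paths(path)
        _load_tsv_nodes(graph, nodes_path)
        _load_tsv_edges(graph, edges_path)
    elif fmt == "json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        for e in doc["entities"]:
            graph.upsert_entity(
                Entity(e["id"], e["label"], e["etype"], set(e.get("aliases", ())))
            )
        for r in doc["relations"]:
            graph.upsert_relation(
                Relation(r["source"], r["target"], r["rtype"], r.get("weight"))
            )
    else:  # graphml
        g = nx.read_graphml(path)
        for node, attrs in g.nodes(data=True):
            aliases = attrs.get("aliases", "")
            graph.upsert_entity(
                Entity(
                    str(node),
                    attrs.get("label", str(node)),
                    attrs.get("etype", "attribute"),
                    set(aliases.split("|")) - {""} if aliases else set(),
                )
            )
        for u, v, attrs in g.edges(data=True):
            graph.upsert_relation(
                Relation(str(u), str(v), attrs.get("rtype", "related"), attrs.get("weight"))
            )
    return graph


def _load_tsv_nodes(graph: KnowledgeGraph, path: Path) -> None:
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _NODE_HEADER:
            raise GraphError(f"{path}:1: bad node header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise GraphError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            id_, label, etype, aliases = parts
            try:
                graph.upsert_entity(
                    Entity(id_, label, etype, set(aliases.split("|")) - {""})
                )
            except GraphError as exc:
                raise GraphError(f"{path}:{lineno}: {exc}") from None


def _load_tsv_edges(graph: KnowledgeGraph, path: Path) -> None:
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _EDGE_HEADER:
            raise GraphError(f"{path}:1: bad edge header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise GraphError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            source, target, rtype, weight = parts
            try:
                graph.upsert_relation(
                    Relation(source, target, rtype, float(weight) if weight else None)
                )
            except (GraphError, ValueError) as exc:
                raise GraphError(f"{path}:{lineno}: {exc}") from None
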