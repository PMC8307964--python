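"""Typed multigraph data model for biomedical knowledge graphs.

A :class:`KnowledgeGraph` holds typed entities (genes, diseases, compounds,
...) connected by labeled edges.  Edges form a multiset: two entities may be
linked by several parallel edges carrying different relation labels (a
curated ``gene_gene`` edge and a literature ``co_occur`` edge can coexist),
and duplicate edges are preserved rather than collapsed.  Storage is an
undirected :class:`networkx.MultiGraph`; the orientation found in source
files is kept as edge metadata but every query (degree, ego networks, path
enumeration) treats edges as undirected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

from .errors import (
    ConflictError,
    EntityNotFoundError,
    ParameterError,
    ReferentialError,
    SelfLoopError,
)

#: Closed vocabulary of entity types: the union of the curated-graph types
#: (compound, phenotype, gene, ...) and the literature-annotation types
#: (disease, chemical, species, mutations, cell lines, ...).
ENTITY_TYPES: frozenset[str] = frozenset(
    {
        "compound",
        "phenotype",
        "gene",
        "biological_process",
        "enzyme_class",
        "go",
        "pathway",
        "organism",
        "tissue",
        "disease",
        "chemical",
        "species",
        "protein_mutation",
        "snp",
        "dna_mutation",
        "cell_line",
        "genus",
        "strain",
    }
)

#: The 27 curated relation labels of the chemogenomic source graph.
AG_RELATION_LABELS: tuple[str, ...] = (
    "compound_gene",
    "gene_disease",
    "compound_adverse_effect",
    "gene_gene",
    "is_a_phenotype",
    "gene_biologicalprocess",
    "gene_cellularcomponent",
    "gene_molecularfunction",
    "gene_tissue",
    "pathway_gene",
    "compound_indication",
    "instance_of",
    "is_a_ec",
    "changes_with",
    "repurposed_indication",
    "pathway_compound",
    "pathway_cellularcomponent",
    "part_of",
    "gene_ec",
    "pathway_contains_pathway",
    "canonical_target",
    "positively_regulates",
    "negatively_regulates",
    "regulates",
    "has_part",
    "occurs_in",
    "gene_go",
)

#: Literature co-mention label, weighted by supporting-document count.
CO_OCCUR = "co_occur"

#: Full admissible label vocabulary: 27 curated labels + ``co_occur``.
RELATION_LABELS: frozenset[str] = frozenset(AG_RELATION_LABELS) | {CO_OCCUR}


def normalize_label(label: str) -> str:
    """Lowercase and strip a relation label (source files print both cases)."""
    return label.strip().lower()


def validate_entity_type(etype: str, allow_unknown: bool = False) -> str:
    etype = etype.strip().lower().replace(" ", "_")
    if etype not in ENTITY_TYPES and not allow_unknown:
        raise ParameterError(f"unknown entity type: {etype!r}")
    return etype


def validate_relation_label(label: str, allow_unknown: bool = False) -> str:
    label = normalize_label(label)
    if label not in RELATION_LABELS and not allow_unknown:
        raise ParameterError(f"unknown relation label: {label!r}")
    return label


@dataclass(frozen=True)
class Entity:
    """A typed node: a gene, disease, compound, ... with its synonym set.

    ``name`` must already be in normalized form (lowercase, underscores
    mapped to spaces, whitespace collapsed — see
    :func:`kgpathrank.merge.normalize_name`).
    """

    entity_id: str
    name: str
    etype: str
    synonyms: frozenset[str] = frozenset()
    sources: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.name:
            raise ParameterError("entity name must be non-empty")


@dataclass(frozen=True)
class Edge:
    """A labeled edge of the multigraph.

    ``weight`` is the supporting-document count for ``co_occur`` edges and 1
    for curated relations.  ``head``/``tail`` record the stored orientation;
    traversal ignores it.
    """

    head: str
    tail: str
    label: str
    weight: float = 1.0
    directed: bool = False

    def __post_init__(self):
        if self.head == self.tail:
            raise SelfLoopError(f"self-loop rejected: {self.head!r}")
        if self.weight < 1:
            raise ParameterError(f"edge weight must be >= 1, got {self.weight}")


class KnowledgeGraph:
    """Typed multigraph of entities and labeled edges.

    Parallel edges (distinct labels, or duplicate provenance of the same
    label) coexist; removal of an entity removes its incident edges.
    """

    def __init__(self):
        self._g = nx.MultiGraph()
        self._entities: dict[str, Entity] = {}

    # -- entities ---------------------------------------------------------

    def add_entity(self, e: Entity) -> None:
        """Add an entity; idempotent for an identical re-add.

        Raises :class:`ConflictError` if ``e.entity_id`` is already present
        with a different type (or any differing field).
        """
        existing = self._entities.get(e.entity_id)
        if existing is not None:
            if existing == e:
                return
            if existing.etype != e.etype:
                raise ConflictError(
                    f"entity {e.entity_id!r} already present as "
                    f"{existing.etype!r}, cannot re-add as {e.etype!r}"
                )
            raise ConflictError(
                f"entity {e.entity_id!r} already present with different fields"
            )
        self._entities[e.entity_id] = e
        self._g.add_node(e.entity_id)

    def remove_entity(self, entity_id: str) -> None:
        self._require(entity_id)
        self._g.remove_node(entity_id)  # drops incident edges
        del self._entities[entity_id]

    def entity(self, entity_id: str) -> Entity:
        self._require(entity_id)
        return self._entities[entity_id]

    def has_entity(self, entity_id: str) -> bool:
        return entity_id in self._entities

    def entities(self) -> Iterator[Entity]:
        return iter(self._entities.values())

    @property
    def entity_count(self) -> int:
        return len(self._entities)

    def entity_counts_by_type(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self._entities.values():
            counts[e.etype] = counts.get(e.etype, 0) + 1
        return counts

    # -- edges ------------------------------------------------------------

    def add_edge(self, edge: Edge) -> None:
        """Append an edge to the multiset.

        Duplicates are preserved (one more parallel instance).  Both
        endpoints must already exist.
        """
        for end in (edge.head, edge.tail):
            if end not in self._entities:
                raise ReferentialError(f"edge endpoint not in graph: {end!r}")
        self._g.add_edge(
            edge.head,
            edge.tail,
            label=edge.label,
            weight=edge.weight,
            head=edge.head,
            directed=edge.directed,
        )

    def edges(self) -> Iterator[Edge]:
        for u, v, data in self._g.edges(data=True):
            head = data.get("head", u)
            tail = v if head == u else u
            yield Edge(
                head=head,
                tail=tail,
                label=data["label"],
                weight=data["weight"],
                directed=data.get("directed", False),
            )

    @property
    def edge_count(self) -> int:
        return self._g.number_of_edges()

    def edge_counts_by_label(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, _, data in self._g.edges(data=True):
            counts[data["label"]] = counts.get(data["label"], 0) + 1
        return counts

    def edges_between(self, a: str, b: str) -> list[Edge]:
        """All parallel edges between two entities (empty if none)."""
        if not self._g.has_edge(a, b):
            return []
        out = []
        for data in self._g[a][b].values():
            head = data.get("head", a)
            tail = b if head == a else a
            out.append(
                Edge(head=head, tail=tail, label=data["label"],
                     weight=data["weight"], directed=data.get("directed", False))
            )
        return out

    # -- queries ----------------------------------------------------------

    def degree(self, entity_id: str) -> int:
        """Number of *distinct* neighboring entities.

        Parallel edges do not inflate degree: a node linked to one neighbor
        by three edges has degree 1.  This is the convention used when node
        size encodes connectivity in rendered subgraphs.
        """
        self._require(entity_id)
        return len(self._g.adj[entity_id])

    def neighbors(self, entity_id: str) -> list[str]:
        self._require(entity_id)
        return list(self._g.adj[entity_id])

    def ego_network(self, center: str, radius: int = 1) -> "KnowledgeGraph":
        """Induced subgraph on all entities within ``radius`` undirected hops.

        Every parent-graph edge between retained entities is retained, so
        e.g. a triangle around the center survives intact at radius 1.
        Hop counting ignores labels and weights.
        """
        self._require(center)
        if radius < 0:
            raise ParameterError(f"radius must be >= 0, got {radius}")
        within = nx.single_source_shortest_path_length(self._g, center, cutoff=radius)
        return self.induced_subgraph(within.keys())

    def induced_subgraph(self, entity_ids: Iterable[str]) -> "KnowledgeGraph":
        keep = set(entity_ids)
        sub = KnowledgeGraph()
        for eid in keep:
            sub.add_entity(self.entity(eid))
        for u, v, data in self._g.edges(data=True):
            if u in keep and v in keep:
                head = data.get("head", u)
                tail = v if head == u else u
                sub.add_edge(
                    Edge(head=head, tail=tail, label=data["label"],
                         weight=data["weight"],
                         directed=data.get("directed", False))
                )
        return sub

    def find_by_name(self, name: str, etype: str | None = None) -> list[Entity]:
        """Entities whose normalized display name equals ``name``."""
        return [
            e for e in self._entities.values()
            if e.name == name and (etype is None or e.etype == etype)
        ]

    # -- plumbing ----------------------------------------------------------

    @property
    def nx_multigraph(self) -> nx.MultiGraph:
        """The backing undirected multigraph (read-only by convention)."""
        return self._g

    def _require(self, entity_id: str) -> None:
        if entity_id not in self._entities:
            raise EntityNotFoundError(f"unknown entity: {entity_id!r}")

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._entities

    def __repr__(self) -> str:
        return (
            f"KnowledgeGraph(entities={self.entity_count}, "
            f"edges={self.edge_count})"
        )


def entity_key(name: str, etype: str) -> str:
    """Default entity-id scheme: type-qualified normalized name.

    Two mentions with the same surface name but different types (a gene and
    a disease both called "ace") are distinct entities.
    """
    return f"{etype}::{name}"
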