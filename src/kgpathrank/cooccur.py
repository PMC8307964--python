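"""Literature co-occurrence edges from entity-annotated documents.

Two entities that are both mentioned in a publication's title or abstract
receive a ``co_occur`` edge; each such document increases the pair's weight
by one, regardless of how many times either entity is repeated inside the
document.  Counting is therefore per-document binary, and the edge weight is
the number of distinct supporting documents.

Entities are identified by (normalized name, entity type): a gene and a
disease that share a surface name are distinct nodes and can co-occur with
each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .model import CO_OCCUR, Edge, Entity, KnowledgeGraph, entity_key


@dataclass(frozen=True)
class Mention:
    """One annotated entity mention: normalized name, type, character span."""

    name: str
    etype: str
    start: int = 0
    end: int = 0
    identifier: str = ""


@dataclass(frozen=True)
class AnnotatedDocument:
    """One publication's title/abstract with its entity mentions.

    The mentions list may repeat a name; repeats within one document do not
    change co-occurrence weights.
    """

    doc_id: str
    title: str = ""
    abstract: str = ""
    mentions: tuple[Mention, ...] = ()

    def distinct_entities(self) -> set[tuple[str, str]]:
        return {(m.name, m.etype) for m in self.mentions}


def build_cooccurrence(
    docs: Iterable[AnnotatedDocument], min_weight: int = 1
) -> list[Edge]:
    """Co-occurrence edges over a corpus.

    One ``co_occur`` edge per unordered pair of distinct (name, type)
    entities mentioned together in at least ``min_weight`` documents, with
    weight = number of supporting documents.  Pairs are canonicalized
    lexicographically and the output is sorted, so the result is
    deterministic.
    """
    weights: dict[tuple[tuple[str, str], tuple[str, str]], int] = {}
    for doc in docs:
        present = sorted(doc.distinct_entities())
        for a, b in combinations(present, 2):
            weights[(a, b)] = weights.get((a, b), 0) + 1
    edges = []
    for (a, b), w in sorted(weights.items()):
        if w < min_weight:
            continue
        edges.append(
            Edge(
                head=entity_key(*a),
                tail=entity_key(*b),
                label=CO_OCCUR,
                weight=float(w),
            )
        )
    return edges


def cooccurrence_graph(
    docs: Sequence[AnnotatedDocument],
    base: KnowledgeGraph | None = None,
    min_weight: int = 1,
    source_tag: str = "CORD19",
) -> KnowledgeGraph:
    """Graph of all mentioned entities plus their co-occurrence edges.

    Extends ``base`` in place when given (entities added on first mention),
    otherwise starts from an empty graph.
    """
    graph = base if base is not None else KnowledgeGraph()
    for doc in docs:
        for name, etype in sorted(doc.distinct_entities()):
            eid = entity_key(name, etype)
            if not graph.has_entity(eid):
                graph.add_entity(
                    Entity(entity_id=eid, name=name, etype=etype,
                           sources=frozenset({source_tag}))
                )
    for edge in build_cooccurrence(docs, min_weight=min_weight):
        graph.add_edge(edge)
    return graph
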