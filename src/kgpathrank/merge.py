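"""Entity disambiguation against a synonym lexicon, and graph merging.

Surface names harvested from curated edge tables and literature annotations
are noisy: the same gene appears as ``msg1`` in one source and ``cited1`` in
another, the same disease as ``breast carcinoma`` and ``breast cancer``.
Disambiguation maps each (name, type) pair to the best-matching canonical
term of a synonym lexicon, under a string-similarity threshold and a hard
same-type constraint, and the merge step then collapses all entities that
landed on the same canonical term into one node, re-wiring their edges.

The default similarity is normalized Levenshtein, ``1 - dist / max(|a|,
|b|)``, computed with edlib.  The threshold tau is a first-class parameter
(default 0.95): the calibration that produced a production lexicon mapping
is data-dependent and must be re-done per lexicon.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable

import edlib

from .errors import ConflictError, ParameterError
from .model import CO_OCCUR, Edge, Entity, KnowledgeGraph, entity_key

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


def normalize_name(raw: str) -> str:
    """Canonical surface form: lowercase, ``_`` -> space, whitespace collapsed.

    Underscores are treated as spaces because printed path records join
    multi-word names either way ("il-6_receptor" and "il-6 receptor" denote
    the same entity).
    """
    return _WS.sub(" ", raw.replace("_", " ")).strip().lower()


def levenshtein_distance(a: str, b: str) -> int:
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def string_similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity in [0, 1]; 1 iff the strings match.

    Two empty strings are defined as identical (similarity 1).
    """
    if a == b:
        return 1.0
    longest = max(len(a), len(b))
    return 1.0 - levenshtein_distance(a, b) / longest


@dataclass(frozen=True)
class LexiconEntry:
    canonical: str
    etype: str
    synonyms: frozenset[str] = frozenset()

    def surface_forms(self) -> frozenset[str]:
        return self.synonyms | {self.canonical}


class SynonymLexicon:
    """Canonical term -> (type, synonyms). Canonical terms are unique per type.

    A synonym may appear under several canonicals; ties are broken
    deterministically at link time (higher score, then lexicographically
    smaller canonical).
    """

    def __init__(self, entries: Iterable[LexiconEntry] = ()):
        self._entries: dict[tuple[str, str], LexiconEntry] = {}
        self._by_type: dict[str, list[LexiconEntry]] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: LexiconEntry) -> None:
        key = (entry.canonical, entry.etype)
        if key in self._entries:
            raise ConflictError(
                f"duplicate lexicon canonical {entry.canonical!r} "
                f"for type {entry.etype!r}"
            )
        self._entries[key] = entry
        self._by_type.setdefault(entry.etype, []).append(entry)

    def entries_of_type(self, etype: str) -> list[LexiconEntry]:
        return self._by_type.get(etype, [])

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())


#: Optional type-equivalence pairs for linking: the curated graph types
#: "compound"/"organism" and the literature types "chemical"/"species" name
#: overlapping categories, but the merged-graph statistics keep them
#: separate, so the equivalence is off by default.
DEFAULT_TYPE_EQUIVALENCES: frozenset[frozenset[str]] = frozenset(
    {frozenset({"chemical", "compound"}), frozenset({"species", "organism"})}
)


@dataclass
class MergeConfig:
    """Disambiguation parameters.

    similarity_threshold: minimum score tau in [0, 1] for a lexicon link.
    similarity: pluggable symmetric metric on normalized strings.
    require_type_match: fixed true — entities only link to same-type entries.
    allow_type_equivalences: when true, the pairs in ``type_equivalences``
        count as "same type" for linking.
    """

    similarity_threshold: float = 0.95
    similarity: Callable[[str, str], float] = string_similarity
    require_type_match: bool = True
    allow_type_equivalences: bool = False
    type_equivalences: frozenset[frozenset[str]] = DEFAULT_TYPE_EQUIVALENCES

    def __post_init__(self):
        if not 0.0 <= self.similarity_threshold <= 1.0:
            raise ParameterError(
                f"similarity threshold must be in [0, 1], "
                f"got {self.similarity_threshold}"
            )

    def types_compatible(self, a: str, b: str) -> bool:
        if a == b:
            return True
        if self.allow_type_equivalences:
            return frozenset({a, b}) in self.type_equivalences
        return False


@dataclass(frozen=True)
class MappedTerm:
    """One disambiguation decision for a (name, type) pair."""

    canonical: str
    etype: str  # type of the merged entity (lexicon type when linked)
    score: float
    linked: bool  # True when justified by a lexicon entry with score >= tau


class EntityMapping:
    """(name, etype) -> canonical term, with the justifying score."""

    def __init__(self):
        self._map: dict[tuple[str, str], MappedTerm] = {}

    def set(self, name: str, etype: str, term: MappedTerm) -> None:
        self._map[(name, etype)] = term

    def resolve(self, name: str, etype: str) -> MappedTerm:
        """Mapping target, defaulting to self-canonical for unseen entities."""
        got = self._map.get((name, etype))
        if got is None:
            return MappedTerm(canonical=name, etype=etype, score=1.0, linked=False)
        return got

    def items(self):
        return self._map.items()

    def linked_count(self) -> int:
        return sum(1 for t in self._map.values() if t.linked)

    def __len__(self) -> int:
        return len(self._map)


def link_entities(
    entities: Iterable[tuple[str, str]],
    lexicon: SynonymLexicon,
    cfg: MergeConfig | None = None,
) -> EntityMapping:
    """Link each (name, etype) to its best same-type lexicon canonical.

    The score of a lexicon entry is the maximum similarity between the name
    and any of the entry's surface forms (canonical or synonym).  Links
    require score >= tau; exact matches always link.  Ties break on higher
    score, then lexicographically smaller canonical.  Unlinked entities stay
    self-canonical.
    """
    cfg = cfg or MergeConfig()
    tau = cfg.similarity_threshold
    mapping = EntityMapping()
    for name, etype in entities:
        candidate_types = {etype}
        if cfg.allow_type_equivalences:
            for pair in cfg.type_equivalences:
                if etype in pair:
                    candidate_types |= set(pair)
        best: tuple[float, str, str] | None = None  # (-score implicit) score, canonical, ltype
        for ctype in sorted(candidate_types):
            for entry in lexicon.entries_of_type(ctype):
                score = max(
                    cfg.similarity(name, form) for form in entry.surface_forms()
                )
                if score < tau:
                    continue
                cand = (score, entry.canonical, entry.etype)
                if (
                    best is None
                    or cand[0] > best[0]
                    or (cand[0] == best[0] and cand[1] < best[1])
                ):
                    best = cand
        if best is not None:
            score, canonical, ltype = best
            mapping.set(
                name, etype,
                MappedTerm(canonical=canonical, etype=ltype, score=score, linked=True),
            )
        else:
            mapping.set(
                name, etype,
                MappedTerm(canonical=name, etype=etype, score=1.0, linked=False),
            )
    return mapping


@dataclass
class MergeReport:
    """Bookkeeping counters for one merge, for conservation checks."""

    entities_in: int = 0
    entities_out: int = 0
    entities_absorbed: int = 0
    edges_in: int = 0
    edges_out: int = 0
    cooccur_pairs_combined: int = 0
    self_loops_dropped: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def merge_graphs(
    g1: KnowledgeGraph,
    g2: KnowledgeGraph,
    mapping: EntityMapping,
    cfg: MergeConfig | None = None,
    *,
    with_report: bool = False,
):
    """Merge two graphs under an entity mapping.

    Entities resolving to the same (canonical term, type) become one node
    carrying the union of synonyms and sources.  Edges are re-wired to
    canonical endpoints; ``co_occur`` edges between the same canonical pair
    are combined by summing weights, other parallel edges are all kept.
    Edges that collapse into self-loops are dropped (and counted).

    Raises :class:`ConflictError` if lexicon-linked mapping entries of
    incompatible types target the same canonical term.
    """
    cfg = cfg or MergeConfig()

    # conflict check over explicit, lexicon-justified links
    linked_types: dict[str, set[str]] = {}
    for (_, src_type), term in mapping.items():
        if term.linked:
            linked_types.setdefault(term.canonical, set()).add(term.etype)
            if not cfg.types_compatible(src_type, term.etype):
                raise ConflictError(
                    f"entity of type {src_type!r} mapped to canonical "
                    f"{term.canonical!r} of type {term.etype!r}"
                )
    for canonical, types in linked_types.items():
        if len(types) > 1:
            raise ConflictError(
                f"canonical {canonical!r} targeted by links of types {sorted(types)}"
            )

    report = MergeReport()
    merged = KnowledgeGraph()

    # pass 1: canonical entities
    redirect: dict[tuple[int, str], str] = {}  # (graph idx, old id) -> new id
    accumulated: dict[str, Entity] = {}
    for gi, g in enumerate((g1, g2)):
        report.entities_in += g.entity_count
        for e in g.entities():
            term = mapping.resolve(e.name, e.etype)
            new_id = entity_key(term.canonical, term.etype)
            redirect[(gi, e.entity_id)] = new_id
            prev = accumulated.get(new_id)
            synonyms = e.synonyms | ({e.name} if e.name != term.canonical else frozenset())
            if prev is None:
                accumulated[new_id] = Entity(
                    entity_id=new_id,
                    name=term.canonical,
                    etype=term.etype,
                    synonyms=frozenset(synonyms),
                    sources=e.sources,
                )
            else:
                accumulated[new_id] = Entity(
                    entity_id=new_id,
                    name=prev.name,
                    etype=prev.etype,
                    synonyms=prev.synonyms | synonyms,
                    sources=prev.sources | e.sources,
                )
    for e in accumulated.values():
        merged.add_entity(e)
    report.entities_out = merged.entity_count
    report.entities_absorbed = report.entities_in - report.entities_out

    # pass 2: edges; co_occur combined by weight sum, others kept verbatim
    cooccur_weight: dict[tuple[str, str], float] = {}
    cooccur_sources: dict[tuple[str, str], int] = {}
    for gi, g in enumerate((g1, g2)):
        for edge in g.edges():
            report.edges_in += 1
            head = redirect[(gi, edge.head)]
            tail = redirect[(gi, edge.tail)]
            if head == tail:
                report.self_loops_dropped += 1
                continue
            if edge.label == CO_OCCUR:
                pair = (min(head, tail), max(head, tail))
                cooccur_weight[pair] = cooccur_weight.get(pair, 0.0) + edge.weight
                cooccur_sources[pair] = cooccur_sources.get(pair, 0) + 1
            else:
                merged.add_edge(
                    Edge(head=head, tail=tail, label=edge.label,
                         weight=edge.weight, directed=edge.directed)
                )
    for (a, b), w in sorted(cooccur_weight.items()):
        merged.add_edge(Edge(head=a, tail=b, label=CO_OCCUR, weight=w))
        report.cooccur_pairs_combined += cooccur_sources[(a, b)] - 1
    report.edges_out = merged.edge_count

    if report.self_loops_dropped:
        logger.info("merge dropped %d self-loop edge(s)", report.self_loops_dropped)

    if with_report:
        return merged, report
    return merged


def mapping_for_graphs(
    g1: KnowledgeGraph,
    g2: KnowledgeGraph,
    lexicon: SynonymLexicon,
    cfg: MergeConfig | None = None,
) -> EntityMapping:
    """Convenience: link the union of both graphs' (name, type) pairs."""
    pairs = {(e.name, e.etype) for g in (g1, g2) for e in g.entities()}
    return link_entities(sorted(pairs), lexicon, cfg)
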