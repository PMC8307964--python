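"""Fixed-depth path enumeration and embedding-based path scoring.

The usability framework behind drug–gene hypothesis generation: enumerate
all simple paths of an exact depth d (d = number of edges; a depth-2 path
has three nodes) between a source and a target entity under undirected
traversal of the typed multigraph, score each path as the sum of cosine
similarities between word-embedding vectors of consecutive nodes,

    S = sum_{i=1..d} cos(v(n_{i-1}), v(n_i)),      -d <= S <= d,

and keep the paths whose score strictly exceeds the nearest-rank 95th
percentile of the per-depth score distribution.

Parallel edges give distinct paths: the same node sequence appears once per
combination of edge instances (a curated gene_gene edge and a literature
co_occur edge between the same pair are different evidence trails).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import EntityNotFoundError, ParameterError, QueryError
from .model import KnowledgeGraph


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------

class EmbeddingStore:
    """Token -> fixed-dimension real vector; lookups are lowercased."""

    def __init__(self, vectors: dict[str, np.ndarray], dim: int):
        for token, vec in vectors.items():
            if vec.shape != (dim,):
                raise ParameterError(
                    f"vector for {token!r} has dimension {vec.shape}, "
                    f"expected ({dim},)"
                )
        self._vectors = {t.lower(): np.asarray(v, dtype=float)
                         for t, v in vectors.items()}
        self.dim = dim

    def get(self, token: str) -> np.ndarray | None:
        return self._vectors.get(token.lower())

    def raw_vector(self, token: str) -> np.ndarray:
        return self._vectors[token.lower()]

    def __contains__(self, token: str) -> bool:
        return token.lower() in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)

    def tokens(self) -> list[str]:
        return sorted(self._vectors)


def entity_vector(store: EmbeddingStore, name: str) -> np.ndarray | None:
    """Vector for a (possibly multi-word) entity name, or None if OOV.

    The full name is tried first under the store's plausible phrase
    conventions (as-is, underscore-joined, hyphen-joined, concatenated);
    failing that, the mean of the in-vocabulary whitespace tokens is used.
    Returns None when no token is in vocabulary.
    """
    for candidate in (name, name.replace(" ", "_"), name.replace(" ", "-"),
                      name.replace(" ", "")):
        vec = store.get(candidate)
        if vec is not None:
            return vec
    token_vecs = [v for t in name.split() if (v := store.get(t)) is not None]
    if not token_vecs:
        return None
    return np.mean(token_vecs, axis=0)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity u.v / (|u||v|); zero vectors are rejected."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ParameterError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ParameterError("cosine similarity undefined for zero vector")
    return float(np.dot(u, v) / (nu * nv))


# ---------------------------------------------------------------------------
# Paths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Path:
    """A simple path: node names n_0..n_d and labels l_1..l_d, depth d."""

    nodes: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.nodes) != len(self.labels) + 1:
            raise ParameterError(
                f"{len(self.nodes)} nodes require {len(self.nodes) - 1} "
                f"labels, got {len(self.labels)}"
            )
        if len(self.labels) < 1:
            raise ParameterError("a path has at least one edge")
        if len(set(self.nodes)) != len(self.nodes):
            raise ParameterError(f"repeated node in simple path: {self.nodes}")

    @property
    def depth(self) -> int:
        return len(self.labels)

    def steps(self) -> list[tuple[str, str, str]]:
        """(node, label, node) triples along the path, in order."""
        return [
            (self.nodes[i], self.labels[i], self.nodes[i + 1])
            for i in range(self.depth)
        ]

    def reversed(self) -> "Path":
        return Path(nodes=self.nodes[::-1], labels=self.labels[::-1])


@dataclass(frozen=True)
class ScoredPath:
    path: Path
    score: float


@dataclass(frozen=True)
class PathQuery:
    """A source/target path-ranking query over one or more exact depths."""

    source: str
    target: str
    depths: tuple[int, ...] = (2, 3, 4)
    percentile: float = 95.0

    def __post_init__(self):
        if self.source == self.target:
            raise QueryError("source and target must differ")
        if not self.depths or any(d < 1 for d in self.depths):
            raise ParameterError(f"depths must be positive: {self.depths}")
        if not 0.0 < self.percentile < 100.0:
            raise ParameterError(
                f"percentile must be in (0, 100), got {self.percentile}"
            )


def _resolve_endpoint(graph: KnowledgeGraph, name_or_id: str) -> str:
    if graph.has_entity(name_or_id):
        return name_or_id
    matches = graph.find_by_name(name_or_id)
    if not matches:
        raise EntityNotFoundError(f"unknown entity: {name_or_id!r}")
    if len(matches) > 1:
        types = sorted(e.etype for e in matches)
        raise QueryError(
            f"ambiguous entity name {name_or_id!r} (types {types}); "
            f"use a type-qualified entity id"
        )
    return matches[0].entity_id


def enumerate_paths(
    graph: KnowledgeGraph, source: str, target: str, depth: int
) -> list[Path]:
    """All simple paths with exactly ``depth`` edges from source to target.

    Traversal is undirected over the multigraph; paths through distinct
    parallel edge instances are distinct, so the same node sequence can
    appear once per combination of labels.  Output is sorted by node
    sequence then label sequence.
    """
    if depth < 1:
        raise ParameterError(f"depth must be >= 1, got {depth}")
    src = _resolve_endpoint(graph, source)
    tgt = _resolve_endpoint(graph, target)
    if src == tgt:
        raise QueryError("source and target must differ")
    g = graph.nx_multigraph
    paths = []
    for edge_path in nx.all_simple_edge_paths(g, src, tgt, cutoff=depth):
        if len(edge_path) != depth:
            continue
        node_ids = [src]
        labels = []
        for u, v, key in edge_path:
            prev = node_ids[-1]
            node_ids.append(v if u == prev else u)
            labels.append(g[u][v][key]["label"])
        paths.append(
            Path(
                nodes=tuple(graph.entity(n).name for n in node_ids),
                labels=tuple(labels),
            )
        )
    paths.sort(key=lambda p: (p.nodes, p.labels))
    return paths


# ---------------------------------------------------------------------------
# Scoring and selection
# ---------------------------------------------------------------------------

@dataclass
class ScoringDiagnostics:
    """Paths excluded from scoring because a node had no embedding."""

    dropped: int = 0
    dropped_paths: list[Path] = field(default_factory=list)
    missing_nodes: set[str] = field(default_factory=set)


def score_paths(
    paths: Iterable[Path], store: EmbeddingStore
) -> tuple[list[ScoredPath], ScoringDiagnostics]:
    """Score each path as the sum of consecutive-node cosine similarities.

    Paths containing a node with no derivable vector are dropped (summing
    zeros instead would silently favor longer out-of-vocabulary-laden
    paths) and recorded in the diagnostics.  The result is sorted by score
    descending, ties broken by node then label sequence for determinism.
    """
    diagnostics = ScoringDiagnostics()
    vec_cache: dict[str, np.ndarray | None] = {}

    def vec(name: str) -> np.ndarray | None:
        if name not in vec_cache:
            vec_cache[name] = entity_vector(store, name)
        return vec_cache[name]

    scored = []
    for path in paths:
        vectors = [vec(n) for n in path.nodes]
        if any(v is None for v in vectors):
            diagnostics.dropped += 1
            diagnostics.dropped_paths.append(path)
            diagnostics.missing_nodes.update(
                n for n, v in zip(path.nodes, vectors) if v is None
            )
            continue
        score = sum(cosine(a, b) for a, b in zip(vectors, vectors[1:]))
        scored.append(ScoredPath(path=path, score=score))
    scored.sort(key=lambda sp: (-sp.score, sp.path.nodes, sp.path.labels))
    return scored, diagnostics


def top_percentile(
    scored: Sequence[ScoredPath], q: float = 95.0
) -> list[ScoredPath]:
    """Paths whose score strictly exceeds the nearest-rank q-th percentile.

    The percentile value is the ceil(q/100 * n)-th smallest score of the
    multiset; only strictly greater scores are retained (so a fully tied
    distribution retains nothing).  Descending order is preserved.
    """
    if not 0.0 < q < 100.0:
        raise ParameterError(f"percentile must be in (0, 100), got {q}")
    if not scored:
        raise ParameterError("top_percentile requires a non-empty score list")
    ordered = sorted(sp.score for sp in scored)
    rank = math.ceil(q / 100.0 * len(ordered))  # 1-based nearest rank
    cutoff = ordered[rank - 1]
    return [sp for sp in scored if sp.score > cutoff]


def count_distinct_relationships(
    paths: Iterable[Path], typed: bool = True
) -> int:
    """Distinct relationships across all edges of all paths.

    ``typed=True`` counts undirected (node, label, node) triples, so the
    same node pair under two labels counts twice; ``typed=False`` counts
    distinct unordered node pairs regardless of label.
    """
    seen = set()
    for path in paths:
        for a, label, b in path.steps():
            lo, hi = (a, b) if a <= b else (b, a)
            seen.add((lo, label, hi) if typed else (lo, hi))
    return len(seen)


# ---------------------------------------------------------------------------
# End-to-end query
# ---------------------------------------------------------------------------

@dataclass
class DepthReport:
    """Results of one query at one exact depth."""

    depth: int
    path_count: int
    scored: list[ScoredPath]
    top_ranked: list[ScoredPath]
    distinct_relationships_typed: int
    distinct_relationships_untyped: int
    dropped_unembeddable: int

    def to_dict(self) -> dict:
        from .io import render_path_record  # local import: io depends on us

        def rows(items):
            return [
                {"path": render_path_record(sp.path),
                 "score": round(sp.score, 6)}
                for sp in items
            ]

        return {
            "depth": self.depth,
            "path_count": self.path_count,
            "scored_paths": rows(self.scored),
            "top_ranked_paths": rows(self.top_ranked),
            "distinct_relationships_typed": self.distinct_relationships_typed,
            "distinct_relationships_untyped":
                self.distinct_relationships_untyped,
            "dropped_unembeddable": self.dropped_unembeddable,
        }


@dataclass
class PathQueryReport:
    query: PathQuery
    depths: list[DepthReport]

    def to_dict(self) -> dict:
        return {
            "source": self.query.source,
            "target": self.query.target,
            "percentile": self.query.percentile,
            "depths": [d.to_dict() for d in self.depths],
        }


def run_path_query(
    graph: KnowledgeGraph, store: EmbeddingStore, query: PathQuery
) -> PathQueryReport:
    """Enumerate, score, and select top-percentile paths at each depth.

    For each requested depth the report carries the raw path count, scored
    and sorted paths, the top-percentile subset, distinct-relationship
    counts over the top subset (both typed and untyped conventions), and
    the number of paths dropped for missing embeddings.  Identical inputs
    produce identical reports.
    """
    reports = []
    for depth in query.depths:
        paths = enumerate_paths(graph, query.source, query.target, depth)
        scored, diag = score_paths(paths, store)
        top = top_percentile(scored, query.percentile) if scored else []
        reports.append(
            DepthReport(
                depth=depth,
                path_count=len(paths),
                scored=scored,
                top_ranked=top,
                distinct_relationships_typed=count_distinct_relationships(
                    (sp.path for sp in top), typed=True
                ),
                distinct_relationships_untyped=count_distinct_relationships(
                    (sp.path for sp in top), typed=False
                ),
                dropped_unembeddable=diag.dropped,
            )
        )
    return PathQueryReport(query=query, depths=reports)
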