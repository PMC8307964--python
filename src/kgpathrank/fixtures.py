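"""Deterministic synthetic fixtures: graphs, embeddings, corpora, lexica.

Every pipeline stage is testable offline against ground truth it can be
checked back against: a :class:`FixturePlan` states per-type entity counts,
per-label edge densities, planted paths with target per-step cosines, a
pairwise co-mention plan, and a lexicon plan.  Generation is a pure function
of the plan (all randomness flows from ``plan.seed`` through a dedicated
``numpy`` generator; no global state), so identical plans give identical
fixtures byte-for-byte after serialization.

Embedding planting builds a Gram matrix over the constrained entities —
specified entries from the planted cosines, unspecified entries completed by
products along a spanning tree of the constraint graph (exact and positive
semidefinite for acyclic constraint sets) — then factorizes it by
eigendecomposition and verifies every planted cosine to 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path as FsPath

import numpy as np

from .cooccur import AnnotatedDocument, Mention
from .errors import PlanError
from .merge import LexiconEntry, SynonymLexicon, levenshtein_distance, normalize_name
from .model import (
    CO_OCCUR,
    RELATION_LABELS,
    Edge,
    Entity,
    KnowledgeGraph,
    entity_key,
)
from .pathrank import EmbeddingStore, Path, cosine

_EIG_CLIP = -1e-9  # most-negative eigenvalue tolerated before declaring infeasible
_COS_TOL = 1e-6


@dataclass(frozen=True)
class PlantedPath:
    """A path guaranteed present in the synthetic graph, with target cosines."""

    nodes: tuple[tuple[str, str], ...]  # (name, etype) in order
    labels: tuple[str, ...]
    step_cosines: tuple[float, ...]

    def __post_init__(self):
        if len(self.nodes) != len(self.labels) + 1:
            raise PlanError("planted path needs one label per edge")
        if len(self.step_cosines) != len(self.labels):
            raise PlanError("planted path needs one cosine per edge")
        if any(not -1.0 <= c <= 1.0 for c in self.step_cosines):
            raise PlanError("planted cosines must lie in [-1, 1]")
        names = [n for n, _ in self.nodes]
        if len(set(names)) != len(names):
            raise PlanError("planted path must be node-simple")

    def as_path(self) -> Path:
        return Path(nodes=tuple(n for n, _ in self.nodes), labels=self.labels)


@dataclass
class FixturePlan:
    """Everything the generators need, including the seed."""

    seed: int = 0
    entity_counts: dict[str, int] = field(default_factory=dict)
    edge_density: dict[str, float] = field(default_factory=dict)
    planted_paths: tuple[PlantedPath, ...] = ()
    co_mentions: dict[tuple[tuple[str, str], tuple[str, str]], int] = field(
        default_factory=dict
    )
    lexicon_plan: tuple[tuple[str, str, int, int], ...] = ()
    # lexicon_plan rows: (canonical, etype, n_synonyms, max_edits)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _planned_entities(plan: FixturePlan) -> list[tuple[str, str]]:
    """Deterministic (name, etype) roster: counted entities + planted nodes."""
    roster: list[tuple[str, str]] = []
    for etype in sorted(plan.entity_counts):
        n = plan.entity_counts[etype]
        stem = etype.replace("_", "")
        roster.extend((f"{stem}{i:03d}", etype) for i in range(n))
    seen = set(roster)
    for pp in plan.planted_paths:
        for name, etype in pp.nodes:
            key = (normalize_name(name), etype)
            if key not in seen:
                roster.append(key)
                seen.add(key)
    return roster


def make_synthetic_kg(plan: FixturePlan) -> KnowledgeGraph:
    """Graph with the plan's entities, density-sampled edges, planted paths.

    For each relation label with density p, every unordered entity pair
    receives an edge with probability p (density 1.0 gives the complete
    graph on n nodes: n(n-1)/2 edges per label).
    """
    for label, p in plan.edge_density.items():
        if not 0.0 <= p <= 1.0:
            raise PlanError(f"density for {label!r} must be in [0, 1], got {p}")
        if label not in RELATION_LABELS:
            raise PlanError(f"unknown relation label in plan: {label!r}")
    rng = plan.rng()
    graph = KnowledgeGraph()
    roster = _planned_entities(plan)
    for name, etype in roster:
        graph.add_entity(
            Entity(entity_id=entity_key(name, etype), name=name, etype=etype,
                   sources=frozenset({"synthetic"}))
        )
    ids = sorted(entity_key(name, etype) for name, etype in roster)
    for label in sorted(plan.edge_density):
        p = plan.edge_density[label]
        if p == 0.0:
            continue
        for a, b in combinations(ids, 2):
            if rng.random() < p:
                graph.add_edge(Edge(head=a, tail=b, label=label))
    for pp in plan.planted_paths:
        keys = [entity_key(normalize_name(n), t) for n, t in pp.nodes]
        for (a, b), label in zip(zip(keys, keys[1:]), pp.labels):
            present = any(e.label == label for e in graph.edges_between(a, b))
            if not present:
                graph.add_edge(Edge(head=a, tail=b, label=label))
    return graph


def _constraint_gram(names: list[str],
                     constraints: dict[tuple[str, str], float]) -> np.ndarray:
    """Gram matrix honoring pairwise cosine constraints.

    Unspecified entries within a connected component of the constraint graph
    are completed by the product of constraints along a BFS spanning-tree
    path (the Markov completion, PSD for acyclic constraint sets); entries
    across components are zero.
    """
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    adj: dict[str, list[tuple[str, float]]] = {m: [] for m in names}
    for (a, b), c in constraints.items():
        adj[a].append((b, c))
        adj[b].append((a, c))
    gram = np.eye(n)
    visited: set[str] = set()
    for root in names:
        if root in visited:
            continue
        # BFS spanning tree of the component
        tree: dict[str, list[tuple[str, float]]] = {root: []}
        visited.add(root)
        queue = [root]
        while queue:
            u = queue.pop(0)
            for v, c in adj[u]:
                if v not in tree:
                    tree[v] = []
                    tree[u].append((v, c))
                    tree[v].append((u, c))
                    visited.add(v)
                    queue.append(v)
        # product of constraint values along the unique tree path
        for a in tree:
            prod = {a: 1.0}
            stack = [a]
            while stack:
                u = stack.pop()
                for v, c in tree[u]:
                    if v not in prod:
                        prod[v] = prod[u] * c
                        stack.append(v)
            for b, p in prod.items():
                if a != b:
                    gram[idx[a], idx[b]] = p
    # specified entries override the tree completion (matters with cycles)
    for (a, b), c in constraints.items():
        gram[idx[a], idx[b]] = c
        gram[idx[b], idx[a]] = c
    return gram


def make_synthetic_embeddings(
    entities: list[str], dim: int, plan: FixturePlan
) -> EmbeddingStore:
    """Embeddings where every planted pair meets its target cosine to 1e-6.

    Constrained entities get Gram-factorized unit vectors; the remaining
    entities get seeded random unit vectors.  Requires ``dim`` at least the
    number of constrained entities.
    """
    constraints: dict[tuple[str, str], float] = {}
    for pp in plan.planted_paths:
        names = [normalize_name(n) for n, _ in pp.nodes]
        for (a, b), c in zip(zip(names, names[1:]), pp.step_cosines):
            key = (min(a, b), max(a, b))
            if key in constraints and abs(constraints[key] - c) > _COS_TOL:
                raise PlanError(
                    f"conflicting cosine constraints for pair {key}: "
                    f"{constraints[key]} vs {c}"
                )
            constraints[key] = c
    constrained = sorted({n for pair in constraints for n in pair})
    if len(constrained) > dim:
        raise PlanError(
            f"dim {dim} too small for {len(constrained)} constrained entities"
        )
    vectors: dict[str, np.ndarray] = {}
    if constrained:
        gram = _constraint_gram(constrained, constraints)
        eigvals, eigvecs = np.linalg.eigh(gram)
        if eigvals.min() < _EIG_CLIP:
            raise PlanError(
                f"constraint set not positive semidefinite "
                f"(min eigenvalue {eigvals.min():.3g})"
            )
        factors = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
        for i, name in enumerate(constrained):
            vec = np.zeros(dim)
            vec[: factors.shape[1]] = factors[i]
            norm = np.linalg.norm(vec)
            if norm == 0.0:
                raise PlanError(f"degenerate vector for {name!r}")
            vectors[name] = vec / norm
        for (a, b), c in constraints.items():
            got = cosine(vectors[a], vectors[b])
            if abs(got - c) > _COS_TOL:
                raise PlanError(
                    f"infeasible constraint cos({a}, {b}) = {c}; "
                    f"achieved {got:.8f}"
                )
    rng = plan.rng()
    for name in entities:
        key = normalize_name(name)
        if key in vectors:
            continue
        vec = rng.standard_normal(dim)
        vectors[key] = vec / np.linalg.norm(vec)
    return EmbeddingStore(vectors=vectors, dim=dim)


def make_synthetic_documents(plan: FixturePlan) -> list[AnnotatedDocument]:
    """Corpus whose per-pair co-mention document counts equal the plan.

    Each planned pair (a, b) with count k yields k documents mentioning
    exactly a and b, so co-occurrence extraction recovers the plan with no
    incidental pairs.
    """
    docs: list[AnnotatedDocument] = []
    serial = 0
    for pair in sorted(plan.co_mentions):
        (name_a, type_a), (name_b, type_b) = pair
        count = plan.co_mentions[pair]
        if count < 0:
            raise PlanError(f"negative co-mention count for {pair}")
        for _ in range(count):
            serial += 1
            title = f"{name_a} interacts with {name_b}"
            start_b = len(name_a) + len(" interacts with ")
            docs.append(
                AnnotatedDocument(
                    doc_id=f"{90000000 + serial}",
                    title=title,
                    abstract=f"Observed effect of {name_a} on {name_b}.",
                    mentions=(
                        Mention(name=normalize_name(name_a), etype=type_a,
                                start=0, end=len(name_a)),
                        Mention(name=normalize_name(name_b), etype=type_b,
                                start=start_b, end=start_b + len(name_b)),
                    ),
                )
            )
    return docs


_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def make_synthetic_lexicon(plan: FixturePlan) -> SynonymLexicon:
    """Lexicon with synonyms within each entry's edit-distance bound."""
    rng = plan.rng()
    lex = SynonymLexicon()
    for canonical, etype, n_synonyms, max_edits in plan.lexicon_plan:
        canonical = normalize_name(canonical)
        synonyms: set[str] = set()
        attempts = 0
        while len(synonyms) < n_synonyms and attempts < 50 * max(n_synonyms, 1):
            attempts += 1
            cand = _mutate(canonical, int(rng.integers(1, max_edits + 1)), rng)
            if cand != canonical and cand:
                if levenshtein_distance(canonical, cand) <= max_edits:
                    synonyms.add(cand)
        if len(synonyms) < n_synonyms:
            raise PlanError(
                f"could not generate {n_synonyms} synonyms for {canonical!r} "
                f"within {max_edits} edits"
            )
        lex.add(LexiconEntry(canonical=canonical, etype=etype,
                             synonyms=frozenset(synonyms)))
    return lex


def _mutate(word: str, edits: int, rng: np.random.Generator) -> str:
    chars = list(word)
    for _ in range(edits):
        op = rng.integers(0, 3)
        pos = int(rng.integers(0, max(len(chars), 1)))
        letter = _ALPHABET[int(rng.integers(0, 26))]
        if op == 0 and chars:  # substitute
            chars[min(pos, len(chars) - 1)] = letter
        elif op == 1:  # insert
            chars.insert(pos, letter)
        elif chars and len(chars) > 1:  # delete
            chars.pop(min(pos, len(chars) - 1))
    return normalize_name("".join(chars))


def write_fixture_bundle(plan: FixturePlan, out_dir: str | FsPath,
                         embedding_dim: int = 16) -> dict[str, str]:
    """Emit edge table, PubTator corpus, lexicon, and embeddings to disk.

    Returns the mapping of artifact kind to file path.
    """
    from . import io as kio  # deferred: io imports fixtures' sibling modules

    out = FsPath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph = make_synthetic_kg(plan)
    docs = make_synthetic_documents(plan)
    lexicon = make_synthetic_lexicon(plan)
    names = sorted({e.name for e in graph.entities()}
                   | {normalize_name(n) for pair in plan.co_mentions
                      for n, _ in pair})
    store = make_synthetic_embeddings(names, embedding_dim, plan)
    paths = {
        "edges": str(out / "edges.csv"),
        "pubtator": str(out / "corpus.pubtator"),
        "lexicon": str(out / "lexicon.tsv"),
        "embeddings": str(out / "vectors.txt"),
    }
    kio.write_edge_table(graph, paths["edges"])
    kio.write_pubtator(docs, paths["pubtator"])
    kio.write_lexicon(lexicon, paths["lexicon"])
    kio.write_word2vec_text(store, paths["embeddings"])
    return paths
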