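"""Path enumeration, embedding scoring, percentile selection."""

import math

import numpy as np
import pytest

from kgpathrank import (
    EmbeddingStore,
    EntityNotFoundError,
    ParameterError,
    Path,
    PathQuery,
    QueryError,
    cosine,
    count_distinct_relationships,
    entity_vector,
    enumerate_paths,
    run_path_query,
    score_paths,
    top_percentile,
)
from kgpathrank.pathrank import ScoredPath
from conftest import build_graph, random_multigraph


def store_of(dim=2, **vectors):
    return EmbeddingStore(
        {k.replace("_", " "): np.asarray(v, dtype=float)
         for k, v in vectors.items()},
        dim,
    )


class TestCosine:
    def test_identical_unit_vectors(self):
        assert cosine(np.array([1.0, 0.0]), np.array([1.0, 0.0])) == 1.0

    def test_orthogonal(self):
        assert cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_closed_form(self):
        assert cosine(np.array([1.0, 1.0]), np.array([1.0, 0.0])) == \
            pytest.approx(1 / math.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ParameterError):
            cosine(np.zeros(2), np.ones(2))


class TestEntityVector:
    def test_single_token(self):
        store = store_of(ace=[1, 0])
        assert np.allclose(entity_vector(store, "ace"), [1, 0])

    def test_multiword_averages_tokens(self):
        store = store_of(ebola=[1, 0], virus=[0, 1])
        assert np.allclose(entity_vector(store, "ebola virus"), [0.5, 0.5])

    def test_phrase_conventions_tried_first(self):
        store = EmbeddingStore({"ebola_virus": np.array([0.0, 1.0]),
                                "ebola": np.array([1.0, 0.0]),
                                "virus": np.array([1.0, 0.0])}, 2)
        assert np.allclose(entity_vector(store, "ebola virus"), [0, 1])

    def test_all_tokens_oov(self):
        store = store_of(ace=[1, 0])
        assert entity_vector(store, "unseen thing") is None


class TestEnumeratePaths:
    def test_triangle_depth_two(self):
        g = build_graph(
            [("a", "gene"), ("b", "gene"), ("c", "gene")],
            [("a", "b", "co_occur"), ("b", "c", "co_occur"),
             ("a", "c", "co_occur")],
        )
        paths = enumerate_paths(g, "a", "c", 2)
        assert len(paths) == 1
        assert paths[0].nodes == ("a", "b", "c")

    def test_parallel_edges_yield_distinct_paths(self):
        g = build_graph(
            [("a", "gene"), ("b", "gene"), ("c", "gene")],
            [("a", "b", "co_occur"), ("a", "b", "gene_gene"),
             ("b", "c", "co_occur")],
        )
        paths = enumerate_paths(g, "a", "c", 2)
        assert len(paths) == 2
        assert {p.labels for p in paths} == {("co_occur", "co_occur"),
                                             ("gene_gene", "co_occur")}

    def test_no_connection_empty(self):
        g = build_graph([("a", "gene"), ("b", "gene"), ("z", "gene")],
                        [("a", "b", "co_occur")])
        assert enumerate_paths(g, "a", "z", 3) == []

    def test_unknown_endpoint(self):
        g = build_graph([("a", "gene")], [])
        with pytest.raises(EntityNotFoundError):
            enumerate_paths(g, "a", "ghost", 2)

    def test_source_equals_target(self):
        g = build_graph([("a", "gene"), ("b", "gene")], [("a", "b", "co_occur")])
        with pytest.raises(QueryError):
            enumerate_paths(g, "a", "a", 2)

    @pytest.mark.parametrize("depth", [2, 3, 4])
    def test_matches_exhaustive_dfs_oracle(self, rng, depth):
        """Enumeration equals an exhaustive depth-limited DFS on random graphs."""
        for _ in range(25):
            n = int(rng.integers(4, 13))
            g = random_multigraph(rng, n, int(rng.integers(n, 3 * n)),
                                  max_parallel=3)
            ids = sorted(e.entity_id for e in g.entities())
            src, tgt = ids[0], ids[-1]
            got = enumerate_paths(g, src, tgt, depth)
            # multiset check: parallel same-label edges duplicate paths
            expected_multiset = _oracle_multiset(g, src, tgt, depth)
            got_multiset = sorted(
                (tuple(p.nodes), p.labels) for p in got
            )
            assert got_multiset == expected_multiset


def _oracle_multiset(g, src, tgt, depth):
    """Exhaustive edge-instance DFS, returning the sorted path multiset."""
    adjacency = {}
    seen_pairs = set()
    for e in g.edges():
        pair = tuple(sorted((e.head, e.tail)))
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        for k, inst in enumerate(g.edges_between(*pair)):
            adjacency.setdefault(pair[0], []).append((pair[1], inst.label, k))
            adjacency.setdefault(pair[1], []).append((pair[0], inst.label, k))
    out = []

    def recurse(node, visited, labels):
        if len(labels) == depth:
            if node == tgt:
                out.append(
                    (tuple(g.entity(v).name for v in visited), tuple(labels))
                )
            return
        for nxt, label, _ in adjacency.get(node, []):
            if nxt in visited:
                continue
            recurse(nxt, visited + [nxt], labels + [label])

    recurse(src, [src], [])
    return sorted(out)


class TestScorePaths:
    def test_collinear_vectors_score_equals_depth(self):
        store = store_of(a=[1, 0], b=[2, 0], c=[3, 0], d=[0.5, 0])
        p = Path(nodes=("a", "b", "c", "d"),
                 labels=("co_occur",) * 3)
        scored, diag = score_paths([p], store)
        assert scored[0].score == pytest.approx(3.0, abs=1e-9)
        assert diag.dropped == 0

    def test_closed_form_depth_two(self):
        store = store_of(a=[1, 0], b=[1, 1], c=[0, 1])
        p = Path(nodes=("a", "b", "c"), labels=("co_occur",) * 2)
        scored, _ = score_paths([p], store)
        assert scored[0].score == pytest.approx(2 / math.sqrt(2), abs=1e-9)

    def test_unembeddable_path_dropped_with_diagnostics(self):
        store = store_of(a=[1, 0], c=[0, 1])
        good = Path(nodes=("a", "c"), labels=("co_occur",))
        bad = Path(nodes=("a", "zzz", "c"), labels=("co_occur",) * 2)
        scored, diag = score_paths([good, bad], store)
        assert len(scored) == 1
        assert diag.dropped == 1
        assert "zzz" in diag.missing_nodes

    def test_sorted_descending(self, rng):
        store = store_of(a=[1, 0], b=[1, 0.2], c=[0, 1], d=[1, -0.5])
        paths = [Path(nodes=(x, y), labels=("co_occur",))
                 for x in "ab" for y in "cd" if x != y]
        scored, _ = score_paths(paths, store)
        assert [sp.score for sp in scored] == \
            sorted((sp.score for sp in scored), reverse=True)

    def test_score_invariant_under_path_reversal(self, rng):
        dim = 5
        store = EmbeddingStore(
            {f"n{i}": rng.standard_normal(dim) for i in range(6)}, dim
        )
        p = Path(nodes=tuple(f"n{i}" for i in range(6)),
                 labels=("co_occur",) * 5)
        (fwd,), _ = score_paths([p], store)
        (rev,), _ = score_paths([p.reversed()], store)
        assert fwd.score == pytest.approx(rev.score, abs=1e-9)

    def test_score_invariant_under_orthogonal_transform(self, rng):
        dim = 4
        vectors = {f"n{i}": rng.standard_normal(dim) for i in range(5)}
        q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
        rotated = {k: q @ v for k, v in vectors.items()}
        p = Path(nodes=tuple(f"n{i}" for i in range(5)),
                 labels=("co_occur",) * 4)
        (a,), _ = score_paths([p], EmbeddingStore(vectors, dim))
        (b,), _ = score_paths([p], EmbeddingStore(rotated, dim))
        assert a.score == pytest.approx(b.score, abs=1e-9)

    def test_score_bounds(self, rng):
        dim = 3
        store = EmbeddingStore(
            {f"n{i}": rng.standard_normal(dim) for i in range(7)}, dim
        )
        for d in (2, 3, 4):
            p = Path(nodes=tuple(f"n{i}" for i in range(d + 1)),
                     labels=("co_occur",) * d)
            (sp,), _ = score_paths([p], store)
            assert -d - 1e-9 <= sp.score <= d + 1e-9


def scored_list(scores):
    paths = [Path(nodes=(f"s{i}", "t"), labels=("co_occur",))
             for i in range(len(scores))]
    return [ScoredPath(p, float(s)) for p, s in zip(paths, scores)]


class TestTopPercentile:
    def test_202_distinct_scores_retain_10(self):
        retained = top_percentile(scored_list(range(202)), 95)
        assert len(retained) == 10

    def test_one_to_hundred_retains_five(self):
        retained = top_percentile(scored_list(range(1, 101)), 95)
        assert len(retained) == 5
        assert sorted(sp.score for sp in retained) == [96, 97, 98, 99, 100]

    def test_all_tied_retains_nothing(self):
        assert top_percentile(scored_list([1.0] * 20), 95) == []

    @pytest.mark.parametrize("q", [0, 100, -5, 120])
    def test_q_outside_open_interval_rejected(self, q):
        with pytest.raises(ParameterError):
            top_percentile(scored_list([1, 2]), q)

    def test_retained_fraction_bound_for_distinct_scores(self, rng):
        """Retained fraction <= 1 - q/100 + 1/n when all scores differ."""
        for _ in range(20):
            n = int(rng.integers(2, 400))
            q = float(rng.uniform(1, 99))
            scores = rng.permutation(n)  # distinct
            retained = top_percentile(scored_list(scores), q)
            assert len(retained) / n <= 1 - q / 100 + 1 / n + 1e-12


class TestCountDistinctRelationships:
    def test_single_path_two_edges(self):
        p = Path(nodes=("a", "b", "c"), labels=("co_occur", "gene_gene"))
        assert count_distinct_relationships([p]) == 2

    def test_duplicate_paths_do_not_double_count(self):
        p = Path(nodes=("a", "b", "c"), labels=("co_occur", "co_occur"))
        assert count_distinct_relationships([p, p]) == 2

    def test_typed_vs_untyped(self):
        p1 = Path(nodes=("a", "b"), labels=("co_occur",))
        p2 = Path(nodes=("a", "b"), labels=("gene_gene",))
        assert count_distinct_relationships([p1, p2], typed=True) == 2
        assert count_distinct_relationships([p1, p2], typed=False) == 1

    def test_undirected_edge_identity(self):
        p1 = Path(nodes=("a", "b"), labels=("co_occur",))
        p2 = Path(nodes=("b", "a"), labels=("co_occur",))
        assert count_distinct_relationships([p1, p2]) == 1


class TestRunPathQuery:
    def test_planted_best_path_ranks_first(self):
        from kgpathrank import FixturePlan, PlantedPath, make_synthetic_kg, \
            make_synthetic_embeddings
        plan = FixturePlan(
            seed=11,
            entity_counts={"gene": 8},
            edge_density={"co_occur": 0.3},
            planted_paths=(PlantedPath(
                nodes=(("alpha", "gene"), ("bridge", "gene"),
                       ("omega", "chemical")),
                labels=("gene_gene", "co_occur"),
                step_cosines=(0.99, 0.98),
            ),),
        )
        g = make_synthetic_kg(plan)
        store = make_synthetic_embeddings(
            sorted(e.name for e in g.entities()), 16, plan)
        report = run_path_query(
            g, store, PathQuery(source="alpha", target="omega", depths=(2,)))
        (depth2,) = report.depths
        assert depth2.scored[0].path.nodes == ("alpha", "bridge", "omega")
        assert depth2.scored[0].score == pytest.approx(1.97, abs=1e-5)

    def test_disconnected_query_reports_zero_counts(self):
        g = build_graph([("a", "gene"), ("b", "gene"), ("z", "gene")],
                        [("a", "b", "co_occur")])
        store = store_of(a=[1, 0], b=[0, 1], z=[1, 1])
        report = run_path_query(g, store,
                                PathQuery(source="a", target="z",
                                          depths=(2, 3)))
        for d in report.depths:
            assert d.path_count == 0
            assert d.top_ranked == []
            assert d.distinct_relationships_typed == 0

    def test_identical_runs_identical_reports(self, rng):
        g = random_multigraph(rng, 10, 30)
        names = sorted(e.name for e in g.entities())
        store = EmbeddingStore(
            {n: np.random.default_rng(1).standard_normal(4) for n in names}, 4)
        q = PathQuery(source="n0", target="n9", depths=(2, 3))
        import json
        r1 = json.dumps(run_path_query(g, store, q).to_dict(), sort_keys=True)
        r2 = json.dumps(run_path_query(g, store, q).to_dict(), sort_keys=True)
        assert r1 == r2

    def test_query_validation(self):
        with pytest.raises(QueryError):
            PathQuery(source="x", target="x")
        with pytest.raises(ParameterError):
            PathQuery(source="a", target="b", percentile=100)
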