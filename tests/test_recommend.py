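"""RelRA scoring: the worked six-liked-items example, bounds,
monotonicity, oracle equivalence, and baseline behaviour."""

import networkx as nx
import numpy as np
import pytest

import litrec as lr

from oracles import brute_force_relra


@pytest.fixture()
def fig3():
    ratings, graph, candidates = lr.fig3_fixture()
    return ratings, graph, candidates, ratings.items_of("researcher_1")


class TestRelraScore:
    def test_worked_example_scores(self, fig3):
        """Six liked items; candidates related to 2, 3 and 0 of them
        score exactly 2/6, 3/6 and 0."""
        _, graph, candidates, liked = fig3
        scores = [lr.relra_score(liked, c, graph) for c in candidates]
        assert scores == [2 / 6, 3 / 6, 0.0]

    def test_candidate_related_to_all_liked_scores_one(self):
        graph = nx.Graph([("c", f"l{i}") for i in range(4)])
        assert lr.relra_score({f"l{i}" for i in range(4)}, "c", graph) == 1.0

    def test_candidate_absent_from_graph_scores_zero(self):
        assert lr.relra_score({"a", "b"}, "ghost", nx.Graph([("a", "b")])) == 0

    def test_preconditions(self):
        graph = nx.Graph()
        with pytest.raises(lr.ValidationError):
            lr.relra_score(set(), "c", graph)
        with pytest.raises(lr.ValidationError):
            lr.relra_score({"c", "x"}, "c", graph)

    def test_bounds_and_zero_iff_no_edges(self, rng):
        for _ in range(30):
            liked = {f"l{i}" for i in range(int(rng.integers(1, 8)))}
            edges = {
                tuple(sorted((f"n{int(a)}", f"n{int(b)}")))
                for a, b in rng.integers(0, 12, size=(10, 2))
                if a != b
            } | {
                ("c0", item)
                for item in liked
                if rng.random() < 0.3
            }
            graph = nx.Graph(list(edges))
            score = lr.relra_score(liked, "c0", graph)
            assert 0.0 <= score <= 1.0
            has_edge = any(graph.has_edge("c0", item) for item in liked)
            assert (score == 0.0) == (not has_edge)

    def test_monotonicity_in_edges_and_denominator(self):
        liked = {"a", "b", "c"}
        graph = nx.Graph([("x", "a")])
        before = lr.relra_score(liked, "x", graph)
        graph.add_edge("x", "b")
        assert lr.relra_score(liked, "x", graph) > before
        # adding an unrelated liked item strictly lowers the score
        bigger = liked | {"unrelated"}
        assert lr.relra_score(bigger, "x", graph) < lr.relra_score(
            liked, "x", graph
        )

    def test_matches_brute_force_pair_loop(self, rng):
        for _ in range(40):
            nodes = [f"n{i}" for i in range(15)]
            edges = {
                tuple(sorted((nodes[int(a)], nodes[int(b)])))
                for a, b in rng.integers(0, 15, size=(25, 2))
                if a != b
            }
            liked = set(
                nodes[int(i)]
                for i in rng.choice(15, size=int(rng.integers(1, 6)),
                                    replace=False)
            )
            candidate = "cand"
            edges |= {
                tuple(sorted((candidate, nodes[int(i)])))
                for i in rng.integers(0, 15, size=3)
            }
            liked.discard(candidate)
            graph = nx.Graph(list(edges))
            assert lr.relra_score(liked, candidate, graph) == pytest.approx(
                brute_force_relra(liked, candidate, edges)
            )

    def test_parallel_relations_count_once(self):
        records = [
            lr.RelationRecord("a", "c", label="x"),
            lr.RelationRecord("c", "a", label="y"),
        ]
        graph = lr.build_graph(records)
        assert lr.relra_score({"a", "b"}, "c", graph) == 0.5


class TestRecommend:
    def test_worked_example_ranking(self, fig3):
        ratings, graph, candidates, _ = fig3
        result = lr.recommend(
            "researcher_1", ratings, graph, candidates=set(candidates), k=2
        )
        assert result.item_ids() == ["CHEBI_34935", "DOID_2945"]
        assert [s for _, s in result.items] == [3 / 6, 2 / 6]

    def test_min_score_excludes_zero_candidates(self, fig3):
        ratings, graph, candidates, _ = fig3
        result = lr.recommend(
            "researcher_1", ratings, graph, candidates=set(candidates),
            k=5, min_score=0,
        )
        assert "GO_0006954" not in result.item_ids()
        assert len(result.items) == 2

    def test_all_zero_scores_rank_by_curie(self):
        train = lr.RatingsDataset([lr.RatingTriple("u", "liked", 1)])
        cands = {"zeta", "alpha", "mid"}
        result = lr.recommend("u", train, nx.Graph(), candidates=cands, k=3)
        assert result.item_ids() == ["alpha", "mid", "zeta"]

    def test_rated_items_removed_from_pool(self, fig3):
        ratings, graph, candidates, liked = fig3
        result = lr.recommend(
            "researcher_1", ratings, graph,
            candidates=set(candidates) | set(liked), k=10,
        )
        assert not set(result.item_ids()) & set(liked)

    def test_unknown_user_and_bad_k(self, fig3):
        ratings, graph, candidates, _ = fig3
        with pytest.raises(lr.ValidationError):
            lr.recommend("nobody", ratings, graph)
        with pytest.raises(lr.ConfigurationError):
            lr.recommend("researcher_1", ratings, graph, k=0)

    def test_ordering_equals_score_then_sort_oracle(self, rng):
        nodes = [f"n{i:02d}" for i in range(40)]
        edges = [
            (nodes[int(a)], nodes[int(b)])
            for a, b in rng.integers(0, 40, size=(80, 2))
            if a != b
        ]
        graph = nx.Graph(edges)
        liked = set(nodes[:8])
        candidates = set(nodes[10:40])
        train = lr.RatingsDataset(
            lr.RatingTriple("u", i, 1) for i in liked
        )
        result = lr.recommend("u", train, graph, candidates=candidates, k=30)
        expected = sorted(
            ((i, lr.relra_score(liked, i, graph)) for i in candidates - liked),
            key=lambda p: (-p[1], p[0]),
        )
        assert list(result.items) == expected[:30]

    def test_deterministic(self, fig3):
        ratings, graph, candidates, _ = fig3
        runs = [
            lr.recommend("researcher_1", ratings, graph,
                         candidates=set(candidates), k=3)
            for _ in range(3)
        ]
        assert runs[0] == runs[1] == runs[2]


class TestRandomBaseline:
    def setup_method(self):
        self.train = lr.RatingsDataset(
            [lr.RatingTriple("u", "liked", 1)]
        )
        self.cands = {f"c{i}" for i in range(5)}

    def test_pool_sized_k_returns_all(self):
        result = lr.random_recommend(
            "u", self.train, candidates=self.cands, k=5, seed=3
        )
        assert set(result.item_ids()) == self.cands
        assert all(s == 0.0 for _, s in result.items)

    def test_same_seed_identical(self):
        a = lr.random_recommend("u", self.train, self.cands, k=3, seed=11)
        b = lr.random_recommend("u", self.train, self.cands, k=3, seed=11)
        assert a == b

    def test_top1_frequency_uniform_over_seeds(self):
        """Each of 5 candidates lands in top-1 with frequency 0.2 +/- 0.02
        across 10,000 seeds."""
        counts: dict[str, int] = {}
        for seed in range(10_000):
            top = lr.random_recommend(
                "u", self.train, self.cands, k=1, seed=seed
            ).item_ids()[0]
            counts[top] = counts.get(top, 0) + 1
        for c in self.cands:
            assert abs(counts[c] / 10_000 - 0.2) <= 0.02
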