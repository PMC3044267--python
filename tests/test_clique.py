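import numpy as np
import pytest

from uted.clique import (SolveResult, brute_force_clique, from_edges,
                         max_clique, max_weight_clique, read_dimacs)

ENGINES = ["python", "compiled"]


def random_graph(rng, n_max=14):
    n = int(rng.integers(1, n_max + 1))
    p = rng.uniform(0.2, 0.8)
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    w = rng.uniform(0.0, 3.0, size=n).tolist()
    return from_edges(n, edges), w


def assert_is_clique(adj, vertices):
    vs = sorted(vertices)
    for a in range(len(vs)):
        for b in range(a + 1, len(vs)):
            assert (adj[vs[a]] >> vs[b]) & 1


class TestMaxClique:
    @pytest.mark.parametrize("engine", ENGINES)
    def test_triangle(self, engine):
        adj = from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert max_clique(adj, engine=engine).best_value == 3

    @pytest.mark.parametrize("engine", ENGINES)
    def test_isolated_vertices(self, engine):
        assert max_clique([0, 0, 0, 0], engine=engine).best_value == 1

    @pytest.mark.parametrize("engine", ENGINES)
    def test_five_cycle_is_triangle_free(self, engine):
        adj = from_edges(5, [(i, (i + 1) % 5) for i in range(5)])
        # exhaustive check that C5 has no triangle
        assert all(not (adj[i] & adj[j]) & ~((1 << i) | (1 << j))
                   for i in range(5) for j in range(i + 1, 5)
                   if (adj[i] >> j) & 1)
        assert max_clique(adj, engine=engine).best_value == 2

    @pytest.mark.parametrize("engine", ENGINES)
    def test_empty_graph(self, engine):
        res = max_clique([], engine=engine)
        assert res.best_value == 0 and res.best_set == frozenset()


class TestMaxWeightClique:
    @pytest.mark.parametrize("engine", ENGINES)
    def test_weighted_path(self, engine):
        # v0-v1-v2 path, weights 1,3,1: either edge containing v1 scores 4
        adj = from_edges(3, [(0, 1), (1, 2)])
        res = max_weight_clique(adj, [1, 3, 1], engine=engine)
        assert res.best_value == 4
        assert 1 in res.best_set and len(res.best_set) == 2

    @pytest.mark.parametrize("engine", ENGINES)
    def test_unit_weights_reduce_to_cardinality(self, engine):
        rng = np.random.default_rng(5)
        for _ in range(20):
            adj, _ = random_graph(rng)
            a = max_weight_clique(adj, [1.0] * len(adj), engine=engine)
            b = max_clique(adj, engine=engine)
            assert a.best_value == b.best_value

    @pytest.mark.parametrize("engine", ENGINES)
    def test_single_heavy_vertex(self, engine):
        res = max_weight_clique([0], [7.0], engine=engine)
        assert res.best_value == 7.0 and res.best_set == frozenset({0})

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            max_weight_clique([0], [-1.0])


class TestOracleEquivalence:
    def test_brute_force_guard(self):
        with pytest.raises(ValueError):
            brute_force_clique([0] * 21)

    def test_brute_force_trivia(self):
        k4 = from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        assert brute_force_clique(k4).best_value == 4
        assert brute_force_clique([]).best_value == 0

    def test_engines_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            adj, w = random_graph(rng)
            oracle = brute_force_clique(adj, w)
            for engine in ENGINES:
                res = max_weight_clique(adj, w, engine=engine)
                assert res.best_value == pytest.approx(oracle.best_value)
                assert_is_clique(adj, res.best_set)

    def test_engines_bitwise_identical(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            adj, w = random_graph(rng)
            a = max_weight_clique(adj, w, engine="python")
            b = max_weight_clique(adj, w, engine="compiled")
            assert a.best_value == b.best_value
            assert a.best_set == b.best_set

    def test_networkx_cross_check(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(11)
        for _ in range(25):
            adj, w = random_graph(rng)
            # networkx needs integer weights: use integer draws
            wi = [int(x * 10) for x in w]
            g = nx.Graph()
            g.add_nodes_from(range(len(adj)))
            for i in range(len(adj)):
                for j in range(i + 1, len(adj)):
                    if (adj[i] >> j) & 1:
                        g.add_edge(i, j)
            for i in range(len(adj)):
                g.nodes[i]["w"] = wi[i]
            _, nx_val = nx.max_weight_clique(g, weight="w" if any(wi) else None)
            res = max_weight_clique(adj, [float(x) for x in wi])
            if any(wi):
                assert res.best_value == pytest.approx(nx_val)


class TestDeterminismAndAnytime:
    def test_two_runs_identical(self):
        rng = np.random.default_rng(3)
        adj, w = random_graph(rng)
        a = max_weight_clique(adj, w)
        b = max_weight_clique(adj, w)
        assert a.best_value == b.best_value and a.best_set == b.best_set

    @pytest.mark.parametrize("engine", ENGINES)
    def test_timeout_returns_valid_incumbent(self, engine):
        rng = np.random.default_rng(9)
        edges = [(i, j) for i in range(60) for j in range(i + 1, 60)
                 if rng.random() < 0.7]
        adj = from_edges(60, edges)
        w = rng.uniform(0, 3, size=60).tolist()
        res = max_weight_clique(adj, w, timeout=0.0, engine=engine)
        # incumbent may be empty but must be a clique and consistent
        assert_is_clique(adj, res.best_set)
        assert res.best_value == pytest.approx(
            sum(w[v] for v in res.best_set))

    @pytest.mark.parametrize("engine", ENGINES)
    def test_warm_start_does_not_change_optimum(self, engine):
        rng = np.random.default_rng(13)
        for _ in range(15):
            adj, w = random_graph(rng)
            base = max_weight_clique(adj, w, engine=engine)
            # seed with any single vertex (always a clique)
            seeded = max_weight_clique(adj, w, engine=engine,
                                       initial=[len(adj) - 1])
            assert seeded.best_value == pytest.approx(base.best_value)
            assert_is_clique(adj, seeded.best_set)

    def test_warm_start_rejects_non_clique(self):
        adj = from_edges(3, [(0, 1)])
        with pytest.raises(ValueError, match="initial"):
            max_weight_clique(adj, [1, 1, 1], initial=[0, 2])

    def test_dimacs_reader(self):
        adj = read_dimacs("c comment\np edge 3 2\ne 1 2\ne 2 3\n")
        assert adj == from_edges(3, [(0, 1), (1, 2)])
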