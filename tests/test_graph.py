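import itertools

import numpy as np
import pytest

from hemianet.graph import (
    ThresholdedGraph,
    betweenness,
    characteristic_path_length,
    clustering,
    node_strength,
    proportional_threshold,
)


def _graph(adj):
    adj = np.asarray(adj, dtype=int)
    return ThresholdedGraph(adjacency=adj, retained_fraction=1.0,
                            labels=[f"n{i}" for i in range(adj.shape[0])])


def _random_graph(k, density, seed):
    r = np.random.default_rng(seed)
    adj = np.zeros((k, k), dtype=int)
    iu = np.triu_indices(k, 1)
    mask = r.random(len(iu[0])) < density
    adj[iu[0][mask], iu[1][mask]] = 1
    return _graph(adj + adj.T)


# --- independent brute-force oracles ---------------------------------------

def floyd_warshall(adj):
    k = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for m in range(k):
        for i in range(k):
            for j in range(k):
                d[i, j] = min(d[i, j], d[i, m] + d[m, j])
    return d


def cpl_oracle(adj):
    """Finite-distance node averages; isolated nodes contribute 0."""
    d = floyd_warshall(adj)
    k = adj.shape[0]
    li = []
    for i in range(k):
        row = [d[i, j] for j in range(k) if j != i and np.isfinite(d[i, j])]
        li.append(np.mean(row) if row else 0.0)
    return float(np.mean(li))


def clustering_oracle(adj):
    """Triangle enumeration by triple loop."""
    k = adj.shape[0]
    ci = np.zeros(k)
    for i in range(k):
        nbrs = [j for j in range(k) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        links = sum(
            adj[a, b] for a, b in itertools.combinations(nbrs, 2)
        )
        ci[i] = 2.0 * links / (len(nbrs) * (len(nbrs) - 1))
    return ci


def betweenness_oracle(adj):
    """Enumerate every shortest path of every pair explicitly."""
    k = adj.shape[0]
    d = floyd_warshall(adj)
    bc = np.zeros(k)

    def all_shortest_paths(s, t):
        if not np.isfinite(d[s, t]):
            return []
        paths, stack = [], [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                paths.append(path)
                continue
            for nxt in range(k):
                if adj[node, nxt] and d[s, nxt] == len(path) and \
                        d[s, nxt] + d[nxt, t] == d[s, t]:
                    stack.append((nxt, path + [nxt]))
        return paths

    for s in range(k):
        for t in range(s + 1, k):
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


# --- proportional threshold -------------------------------------------------

class TestProportionalThreshold:
    def test_keeps_two_largest_of_six(self):
        w = np.zeros((4, 4))
        vals = [0.9, 0.8, 0.3, 0.2, 0.1, 0.05]
        for (i, j), v in zip(itertools.combinations(range(4), 2), vals):
            w[i, j] = w[j, i] = v
        g = proportional_threshold(w, 0.3)  # round(1.8) = 2 edges
        assert g.n_edges == 2
        assert g.adjacency[0, 1] == 1 and g.adjacency[0, 2] == 1

    def test_p_one_keeps_all(self, random_symmetric):
        g = proportional_threshold(random_symmetric(7, 0), 1.0)
        assert g.n_edges == 7 * 6 // 2

    def test_equal_weights_tie_broken_by_index(self):
        w = np.ones((4, 4)) - np.eye(4)
        g = proportional_threshold(w, 0.5)  # round(3) edges
        assert g.n_edges == 3
        # ascending (row, col) order: (0,1), (0,2), (0,3)
        assert g.adjacency[0, 1] == g.adjacency[0, 2] == g.adjacency[0, 3] == 1

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, p, random_symmetric):
        with pytest.raises(ValueError):
            proportional_threshold(random_symmetric(4, 1), p)

    def test_monotone_transform_invariance(self, random_symmetric):
        w = random_symmetric(12, 5)
        a = proportional_threshold(w, 0.3).adjacency
        b = proportional_threshold(np.sqrt(w) * 4.2, 0.3).adjacency
        assert np.array_equal(a, b)


class TestNodeStrength:
    def test_triangle_sums(self):
        w = np.array([[0, 0.2, 0.3], [0.2, 0, 0.5], [0.3, 0.5, 0]])
        s = node_strength(w).strength
        assert np.allclose(s, [0.5, 0.7, 0.8])

    def test_zero_matrix(self):
        assert np.allclose(node_strength(np.zeros((5, 5))).strength, 0.0)

    def test_matches_row_sum_oracle(self, random_symmetric):
        w = random_symmetric(20, 9)
        assert np.allclose(node_strength(w).strength, w.sum(axis=1))

    def test_negative_weights_rejected(self):
        w = -np.ones((3, 3)) + np.eye(3)
        with pytest.raises(ValueError, match="negative"):
            node_strength(w)


class TestClustering:
    def test_complete_triangle(self):
        g = _graph(np.ones((3, 3)) - np.eye(3))
        node, global_c = clustering(g)
        assert np.allclose(node.clustering, 1.0)
        assert global_c == 1.0

    def test_star_all_zero(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1:] = adj[1:, 0] = 1
        node, global_c = clustering(_graph(adj))
        assert np.allclose(node.clustering, 0.0)
        assert global_c == 0.0

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_triangle_enumeration_oracle(self, seed):
        g = _random_graph(10, 0.4, seed)
        node, global_c = clustering(g)
        expected = clustering_oracle(g.adjacency)
        assert np.allclose(node.clustering, expected)
        assert global_c == pytest.approx(expected.mean())


class TestCharacteristicPathLength:
    def test_three_node_path(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        m = characteristic_path_length(_graph(adj))
        assert m.cpl == pytest.approx(4.0 / 3.0)
        assert np.allclose(m.per_node_path_length, [1.5, 1.0, 1.5])

    def test_complete_triangle(self):
        m = characteristic_path_length(_graph(np.ones((3, 3)) - np.eye(3)))
        assert m.cpl == 1.0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            characteristic_path_length(_graph(np.zeros((4, 4))))

    def test_isolated_node_flagged(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        m = characteristic_path_length(_graph(adj))
        assert m.isolated_nodes == ["n2"]
        assert m.cpl == pytest.approx((1.0 + 1.0 + 0.0) / 3.0)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_floyd_warshall_oracle(self, seed):
        g = _random_graph(12, 0.25, seed)
        if g.adjacency.sum() == 0:
            return
        assert characteristic_path_length(g).cpl == pytest.approx(
            cpl_oracle(g.adjacency)
        )


class TestBetweenness:
    def test_three_node_path(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        b = betweenness(_graph(adj)).betweenness
        assert np.allclose(b, [0.0, 1.0, 0.0])

    def test_complete_triangle_zero(self):
        b = betweenness(_graph(np.ones((3, 3)) - np.eye(3))).betweenness
        assert np.allclose(b, 0.0)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_path_enumeration_oracle(self, seed):
        g = _random_graph(9, 0.35, seed)
        assert np.allclose(
            betweenness(g).betweenness, betweenness_oracle(g.adjacency)
        )

    def test_normalization_switch(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        b = betweenness(_graph(adj), normalized=True).betweenness
        assert b[1] == pytest.approx(1.0)  # 1 / ((n-1)(n-2)/2) = 1/1


class TestGraphInvariants:
    def test_permutation_equivariance(self, random_symmetric):
        w = random_symmetric(10, 3)
        perm = np.random.default_rng(7).permutation(10)
        g1 = proportional_threshold(w, 0.3)
        g2 = proportional_threshold(w[np.ix_(perm, perm)], 0.3)
        b1 = betweenness(g1).betweenness
        b2 = betweenness(g2).betweenness
        # note: permuting may flip tie-breaks only for exactly equal weights;
        # random continuous weights have none
        assert np.allclose(b1[perm], b2)
        c1 = clustering(g1)[0].clustering
        c2 = clustering(g2)[0].clustering
        assert np.allclose(c1[perm], c2)

    def test_adding_edge_never_lengthens_paths(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            g = _random_graph(8, 0.3, int(rng.integers(1e6)))
            if g.adjacency.sum() == 0:
                continue
            d0 = floyd_warshall(g.adjacency)
            adj = g.adjacency.copy()
            free = np.argwhere(np.triu(adj == 0, 1))
            if len(free) == 0:
                continue
            i, j = free[rng.integers(len(free))]
            adj[i, j] = adj[j, i] = 1
            d1 = floyd_warshall(adj)
            assert (d1 <= d0 + 1e-12).all()
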