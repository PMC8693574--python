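"""MST construction (Kruskal, 1/PLI costs) and the six tree measures."""

import itertools

import networkx as nx
import numpy as np
import pytest

from plinet.connectivity import ConnectivityMatrix
from plinet.montage import CANONICAL_16
from plinet.mst import MSTResult, build_mst, mst_from_matrix, mst_measures, top_nodes

LABELS = CANONICAL_16


def matrix(vals, labels=None):
    vals = np.asarray(vals, dtype=float)
    return ConnectivityMatrix(values=vals,
                              channel_labels=labels or LABELS[: vals.shape[0]])


def tree_from_edges(edges, labels):
    return MSTResult(channel_labels=tuple(labels), edges=[tuple(sorted(e))
                                                          for e in edges])


def star_tree(center="P3", labels=LABELS):
    return tree_from_edges([(center, lab) for lab in labels if lab != center],
                           labels)


def path_tree(labels=LABELS):
    return tree_from_edges(list(zip(labels, labels[1:])), labels)


def total_cost(tree):
    return sum(1.0 / w for w in tree.edge_weights.values())


def all_spanning_trees_cost(w):
    """Oracle: minimum cost over every labelled spanning tree (Prüfer)."""
    n = w.shape[0]
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        # decode the Prüfer sequence into an edge list
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        ptr = 0
        leaf = -1
        edges = []
        seq_list = list(seq)
        avail = degree[:]
        import heapq
        leaves = [i for i in range(n) if avail[i] == 1]
        heapq.heapify(leaves)
        for v in seq_list:
            u = heapq.heappop(leaves)
            edges.append((u, v))
            avail[v] -= 1
            if avail[v] == 1:
                heapq.heappush(leaves, v)
        u = heapq.heappop(leaves)
        v = heapq.heappop(leaves)
        edges.append((u, v))
        cost = sum(1.0 / w[a, b] for a, b in edges)
        best = min(best, cost)
    return best


class TestBuildMst:
    def test_three_node_example(self):
        # PLI {AB:0.9, BC:0.8, AC:0.5}: the two strongest edges win
        vals = np.array([[0, 0.9, 0.5], [0.9, 0, 0.8], [0.5, 0.8, 0]])
        tree = build_mst(matrix(vals, labels=("A", "B", "C")))
        assert set(tree.edges) == {("A", "B"), ("B", "C")}

    def test_sixteen_nodes_gives_spanning_tree(self, random_matrix_factory):
        tree = build_mst(random_matrix_factory())
        assert len(tree.edges) == 15
        g = nx.Graph(tree.edges)
        assert nx.is_connected(g) and nx.is_tree(g)
        assert set(g.nodes) == set(LABELS)

    def test_equal_weights_tie_break_is_deterministic(self):
        cm = matrix(0.5 * (1 - np.eye(16)))
        t1 = build_mst(cm)
        t2 = build_mst(cm)
        assert t1.edges == t2.edges
        # lexicographic tie-break: first edge is the alphabetically first pair
        assert t1.edges[0] == tuple(sorted(LABELS)[:2])

    def test_cost_matches_networkx(self, random_matrix_factory):
        for _ in range(25):
            cm = random_matrix_factory()
            tree = build_mst(cm)
            g = nx.Graph()
            for i, a in enumerate(LABELS):
                for j in range(i + 1, 16):
                    g.add_edge(a, LABELS[j], weight=1.0 / cm.values[i, j])
            nx_cost = nx.minimum_spanning_tree(g, algorithm="kruskal").size(
                weight="weight")
            assert total_cost(tree) == pytest.approx(nx_cost)

    def test_cost_matches_exhaustive_enumeration_small_n(self, rng):
        for n in (5, 6, 7):
            for _ in range(3):
                vals = rng.uniform(0.1, 1.0, (n, n))
                vals = np.triu(vals, 1)
                vals = vals + vals.T
                tree = build_mst(matrix(vals))
                idx = {lab: i for i, lab in enumerate(LABELS[:n])}
                cost = sum(1.0 / vals[idx[a], idx[b]] for a, b in tree.edges)
                assert cost == pytest.approx(all_spanning_trees_cost(vals))

    def test_cost_beats_random_spanning_trees(self, random_matrix_factory, rng):
        cm = random_matrix_factory()
        tree = build_mst(cm)
        idx = {lab: i for i, lab in enumerate(LABELS)}
        best_random = np.inf
        for _ in range(200):
            g = nx.Graph()
            order = rng.permutation(16)
            for k in range(1, 16):
                attach = order[rng.integers(0, k)]
                g.add_edge(int(order[k]), int(attach))
            cost = sum(1.0 / cm.values[a, b] for a, b in g.edges)
            best_random = min(best_random, cost)
        assert total_cost(tree) <= best_random + 1e-12

    def test_monotone_loading_forces_edge_in(self, random_matrix_factory):
        cm = random_matrix_factory(high=0.8)
        vals = cm.values.copy()
        vals[2, 9] = vals[9, 2] = 0.99  # strictly above every other weight
        tree = build_mst(matrix(vals))
        assert tuple(sorted((LABELS[2], LABELS[9]))) in tree.edges

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            build_mst(matrix(np.zeros((1, 1)), labels=("A",)))


class TestMeasures:
    def test_star_measures_match_exhaustive_path_counts(self):
        tree = mst_measures(star_tree())
        assert tree.Degr == pytest.approx(1.0)
        assert tree.Leaf == pytest.approx(15 / 16)
        assert tree.Diam == pytest.approx(2 / 15)
        assert tree.BC == pytest.approx(105 / 120)   # C(15,2)/C(16,2)
        assert tree.TH == pytest.approx(15 / (2 * 15 * (105 / 120)))
        assert tree.Ecc == pytest.approx((1 + 15 * 2) / 16 / 15)

    def test_path_measures(self):
        tree = mst_measures(path_tree())
        assert tree.Leaf == pytest.approx(2 / 16)
        assert tree.Diam == pytest.approx(1.0)
        assert tree.BC == pytest.approx(56 / 120)    # max i*(15-i) = 7*8
        assert tree.TH == pytest.approx(2 / (2 * 15 * (56 / 120)))

    def test_handshake_identity(self, random_matrix_factory):
        tree = mst_from_matrix(random_matrix_factory())
        assert sum(tree.degree_fraction.values()) == pytest.approx(2.0)

    def test_tree_hierarchy_identity_exact(self, random_matrix_factory):
        tree = mst_from_matrix(random_matrix_factory())
        leaf_number = tree.Leaf * 16
        assert tree.TH * (2 * 15 * tree.BC) == pytest.approx(leaf_number,
                                                             abs=1e-12)

    def test_eccentricity_bounded_by_diameter(self, random_matrix_factory):
        tree = mst_from_matrix(random_matrix_factory())
        assert max(tree.ecc_node.values()) <= tree.Diam + 1e-12
        assert 0 < tree.Degr <= 1 and 0 < tree.BC <= 1
        assert 0 < tree.Leaf <= 1 and 0 < tree.Diam <= 1

    def test_betweenness_matches_bfs_path_tracing_oracle(self, rng):
        for _ in range(100):
            g = nx.random_labeled_tree(16, seed=int(rng.integers(2 ** 31)))
            g = nx.relabel_nodes(g, dict(enumerate(LABELS)))
            tree = mst_measures(tree_from_edges(g.edges, LABELS))
            for node in LABELS:
                count = 0
                for a, b in itertools.combinations(LABELS, 2):
                    path = nx.shortest_path(g, a, b)
                    if node in path[1:-1]:
                        count += 1
                assert tree.bc_node[node] == pytest.approx(count / 120)

    def test_non_tree_input_rejected(self):
        tree = tree_from_edges(list(zip(LABELS, LABELS[1:])), LABELS)
        tree.edges[0] = tree.edges[-1]  # duplicate edge: F3 disconnected
        with pytest.raises(ValueError):
            mst_measures(tree)
        short = tree_from_edges(list(zip(LABELS, LABELS[1:]))[:10], LABELS)
        with pytest.raises(ValueError, match="spanning"):
            mst_measures(short)


class TestTopNodes:
    def test_star_center_wins_both_criteria(self):
        tree = mst_measures(star_tree(center="P3"))
        assert top_nodes(tree) == (["P3"], ["P3"])

    def test_two_equal_hubs_both_returned(self):
        # barbell: two 7-leaf stars joined by an edge between the hubs
        labels = LABELS
        h1, h2 = labels[0], labels[1]
        leaves = labels[2:]
        edges = [(h1, l) for l in leaves[:7]] + [(h2, l) for l in leaves[7:]]
        edges.append((h1, h2))
        tree = mst_measures(tree_from_edges(edges, labels))
        by_deg, by_bc = top_nodes(tree)
        assert set(by_deg) == {h1, h2}
        assert set(by_bc) == {h1, h2}

    def test_path_graph_tie_structure(self):
        tree = mst_measures(path_tree())
        by_deg, by_bc = top_nodes(tree)
        assert set(by_deg) == set(LABELS[1:-1])          # 14 interior nodes
        assert set(by_bc) == {LABELS[7], LABELS[8]}      # two middle nodes
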