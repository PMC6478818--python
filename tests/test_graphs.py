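"""Graph containers, family constructors, enumeration and I/O."""

import itertools

import networkx as nx
import numpy as np
import pytest

import moranet as mn
from moranet.graphs import GraphError


# ---------------------------------------------------------------------------
# kernels and constructors
# ---------------------------------------------------------------------------


def test_kernel_rows_are_stochastic(small_graph_corpus):
    for g in small_graph_corpus:
        rows = np.asarray(g.kernel().matrix.sum(axis=1)).ravel()
        assert np.allclose(rows, 1.0, atol=1e-12), g.family


@pytest.mark.parametrize(
    "n, pair, expected",
    [(3, (0, 1), 0.5), (3, (2, 0), 0.5), (2, (0, 1), 1.0), (2, (1, 0), 1.0)],
)
def test_complete_graph_kernel(n, pair, expected):
    k = mn.make_complete(n).kernel()
    assert k.w(*pair) == pytest.approx(expected, abs=1e-15)


def test_complete_graph_edge_count():
    assert mn.make_complete(8).n_edges == 28


def test_star_kernel_rows():
    k = mn.make_star(4).kernel()
    # a leaf's offspring always lands on the center
    assert k.w(1, 0) == pytest.approx(1.0)
    assert k.w(1, 2) == 0.0
    # the center spreads uniformly over the leaves
    for leaf in (1, 2, 3):
        assert k.w(0, leaf) == pytest.approx(1 / 3)


def test_star_n3_is_path():
    star = mn.make_star(3)
    path = mn.WeightedGraph(3, {(0, 1): 1.0, (0, 2): 1.0})
    assert star.edge_set() == path.edge_set()


def test_bipartite_kernel_with_self_loops():
    g = mn.make_complete_bipartite(4, 2, selfloop_weight=2.0)
    k = g.kernel()
    # large-part vertex: self-loop 2 vs two unit cross edges
    assert k.w(0, 0) == pytest.approx(0.5)
    assert k.w(0, 4) == pytest.approx(0.25)
    assert k.w(0, 5) == pytest.approx(0.25)
    # small-part vertex spreads over the large part only
    assert k.w(4, 0) == pytest.approx(0.25)
    assert k.w(4, 5) == 0.0


@pytest.mark.parametrize(
    "n_large, alpha, expected_small",
    [(8, 1 / 3, 4), (100, 0.5, 10), (1000, 0.1, 501)],
)
def test_balanced_bipartite_part_sizes(n_large, alpha, expected_small):
    g = mn.make_balanced_bipartite(n_large, alpha)
    assert g.n == n_large + expected_small
    assert g.family[3] == expected_small


def test_weighted_bipartite_self_loop_values():
    g = mn.make_weighted_bipartite(100, 1.0)
    assert g.family[3] == 1  # single-vertex small part
    assert g.edges[(0, 0)] == pytest.approx(100**0.5 - 1)  # = 9
    g = mn.make_weighted_bipartite(100, 0.5)
    assert g.family[3] == 10
    assert g.edges[(0, 0)] == pytest.approx(100**0.75 - 10)  # ~ 21.6228


def test_weighted_bipartite_migration_probability():
    # offspring of a large-part vertex leaves for the small part w.p. ~ N^(-alpha/2)
    n, alpha = 400, 0.5
    g = mn.make_weighted_bipartite(n, alpha)
    k = g.kernel()
    s = g.family[3]
    migrate = sum(k.w(0, v) for v in range(n, n + s))
    assert migrate == pytest.approx(n ** (-alpha / 2), rel=0.1)


def test_cycle_is_two_regular():
    g = mn.make_cycle(8)
    assert g.n_edges == 8
    assert all(g.degree(v) == 2 for v in range(8))


def test_random_tree_properties():
    g = mn.make_random_tree(100, seed=7)
    assert g.n_edges == 99  # a connected graph with n-1 edges is a tree
    assert mn.make_random_tree(100, seed=7).edge_set() == g.edge_set()
    assert mn.make_random_tree(100, seed=8).edge_set() != g.edge_set()


def test_star_plus_zero_edges_is_star():
    assert mn.make_star_plus_edges(8, 0, seed=1).edge_set() == mn.make_star(8).edge_set()


def test_erdos_renyi_reproducible_and_connected():
    g1 = mn.make_erdos_renyi(30, 0.15, seed=3)
    g2 = mn.make_erdos_renyi(30, 0.15, seed=3)
    assert g1.edge_set() == g2.edge_set()


def test_erdos_renyi_impossible_connectivity():
    with pytest.raises(GraphError):
        mn.make_erdos_renyi(10, 0.0, seed=0)


@pytest.mark.parametrize(
    "factory",
    [
        lambda: mn.make_complete(1),
        lambda: mn.make_star(2),
        lambda: mn.make_complete_bipartite(2, 3),
        lambda: mn.make_complete_bipartite(3, 2, selfloop_weight=-1.0),
        lambda: mn.make_balanced_bipartite(8, 1.5),
        lambda: mn.WeightedGraph(4, {(0, 1): 1.0, (2, 3): 1.0}),  # disconnected
        lambda: mn.WeightedGraph(3, {(0, 1): 0.0, (1, 2): 1.0}),  # zero weight
    ],
)
def test_invalid_constructions_raise(factory):
    with pytest.raises(GraphError):
        factory()


def test_directed_graph_requires_strong_connectivity():
    with pytest.raises(GraphError):
        mn.WeightedGraph(3, {(0, 1): 1.0, (1, 2): 1.0}, directed=True)
    g = mn.WeightedGraph(3, {(0, 1): 1.0, (1, 2): 1.0, (2, 0): 1.0}, directed=True)
    assert g.kernel().w(1, 2) == 1.0
    assert g.kernel().w(2, 1) == 0.0


# ---------------------------------------------------------------------------
# enumeration and census
# ---------------------------------------------------------------------------


def _brute_force_connected_classes(n: int) -> int:
    """Independent oracle: dedupe all labeled graphs by isomorphism."""
    pairs = list(itertools.combinations(range(n), 2))
    reps: list[nx.Graph] = []
    for bits in range(1 << len(pairs)):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(p for i, p in enumerate(pairs) if bits >> i & 1)
        if not nx.is_connected(g):
            continue
        if not any(nx.is_isomorphic(g, h) for h in reps):
            reps.append(g)
    return len(reps)


@pytest.mark.parametrize("n, expected", [(3, 2), (4, 6), (5, 21)])
def test_enumeration_matches_brute_force(n, expected):
    assert _brute_force_connected_classes(n) == expected
    assert sum(1 for _ in mn.enumerate_connected_graphs(n)) == expected
    assert mn.count_connected_graphs(n) == expected


@pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
def test_census_agrees_with_enumeration(n):
    assert mn.count_connected_graphs(n) == sum(1 for _ in mn.enumerate_connected_graphs(n))


def test_census_known_values():
    assert [mn.count_connected_graphs(k) for k in range(1, 8)] == [1, 1, 2, 6, 21, 112, 853]


def test_enumeration_yields_nonisomorphic_graphs(rng):
    gs = [g.to_networkx() for g in mn.enumerate_connected_graphs(6)]
    idx = rng.choice(len(gs), size=(40, 2))
    for i, j in idx:
        if i != j:
            assert not nx.is_isomorphic(gs[i], gs[j])


def test_enumeration_is_deterministic():
    first = [g.edge_set() for g in mn.enumerate_connected_graphs(5)]
    second = [g.edge_set() for g in mn.enumerate_connected_graphs(5)]
    assert first == second


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def test_graph6_round_trip(tmp_path):
    gs = list(mn.enumerate_connected_graphs(5))
    path = tmp_path / "g5.g6"
    mn.graphs.write_graph6(gs, str(path))
    back = mn.graphs.read_graph6(str(path))
    assert len(back) == len(gs)
    for a, b in zip(gs, back):
        assert nx.is_isomorphic(a.to_networkx(), b.to_networkx())


def test_edgelist_tsv_round_trip(tmp_path):
    g = mn.make_complete_bipartite(4, 2, selfloop_weight=1.5)
    path = tmp_path / "g.tsv"
    mn.graphs.write_edgelist_tsv(g, str(path))
    back = mn.graphs.read_edgelist_tsv(str(path))
    assert back.edges == g.edges
    assert back.n == g.n


def test_edgelist_tsv_directed_round_trip(tmp_path):
    g = mn.WeightedGraph(3, {(0, 1): 1.0, (1, 2): 2.0, (2, 0): 0.5}, directed=True)
    path = tmp_path / "d.tsv"
    mn.graphs.write_edgelist_tsv(g, str(path))
    back = mn.graphs.read_edgelist_tsv(str(path), directed=True)
    assert back.edges == g.edges
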