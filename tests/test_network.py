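"""Ecological network topology, nulls and module preservation vs brute force."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from gutlink import network
from gutlink.graphs import SignedNetwork, from_correlation
from gutlink.linking import detect_modules


def _net_from_edges(edges, n_nodes=None, signs=None):
    g = nx.Graph()
    if n_nodes:
        g.add_nodes_from(range(n_nodes))
    for k, (u, v) in enumerate(edges):
        w = 1.0 if signs is None else float(signs[k])
        g.add_edge(u, v, weight=w, abs_weight=abs(w), sign=1 if w >= 0 else -1)
    return SignedNetwork(g, 0.0)


# -- brute-force oracles -----------------------------------------------------

def brute_avg_clustering(g):
    total = 0.0
    for n in g.nodes:
        nbrs = list(g.neighbors(n))
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
        )
        total += 2.0 * links / (k * (k - 1))
    return total / g.number_of_nodes()


def brute_avg_path(g):
    total, pairs = 0.0, 0
    nodes = list(g.nodes)
    for a, b in itertools.combinations(nodes, 2):
        try:
            total += nx.shortest_path_length(g, a, b)
            pairs += 1
        except nx.NetworkXNoPath:
            continue
    return total / pairs if pairs else float("nan")


def brute_modularity(g, communities):
    m = sum(d["abs_weight"] for _, _, d in g.edges(data=True))
    deg = {n: sum(g[n][v]["abs_weight"] for v in g.neighbors(n)) for n in g.nodes}
    q = 0.0
    for comm in communities:
        for a, b in itertools.product(comm, comm):
            w = g[a][b]["abs_weight"] if g.has_edge(a, b) else 0.0
            q += w - deg[a] * deg[b] / (2 * m)
    return q / (2 * m)


class TestTopology:
    def test_triangle(self):
        net = _net_from_edges([(0, 1), (1, 2), (0, 2)])
        t = network.topology(net)
        assert (t.n_nodes, t.n_edges) == (3, 3)
        assert t.avg_degree == pytest.approx(2.0)
        assert t.avg_clustering == pytest.approx(1.0)
        assert t.avg_path_distance == pytest.approx(1.0)
        assert t.positive_pct == 100.0

    def test_three_node_path_hand_enumeration(self):
        net = _net_from_edges([(0, 1), (1, 2)])
        t = network.topology(net)
        assert t.avg_degree == pytest.approx(4 / 3)
        assert t.avg_clustering == 0.0
        assert t.avg_path_distance == pytest.approx((1 + 1 + 2) / 3)

    def test_matches_brute_force_on_random_graphs(self):
        """All metrics equal an independent brute-force pass, 20 graphs <=12 nodes."""
        for s in range(20):
            rng = np.random.default_rng(s)
            n = int(rng.integers(4, 13))
            p = rng.uniform(0.2, 0.7)
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
            if g.number_of_edges() == 0:
                continue
            signs = rng.choice([-1.0, 1.0], size=g.number_of_edges())
            net = _net_from_edges(list(g.edges), n_nodes=n, signs=signs)
            t = network.topology(net)
            assert t.avg_degree == pytest.approx(2 * g.number_of_edges() / n)
            assert t.avg_clustering == pytest.approx(brute_avg_clustering(net.graph))
            assert t.avg_path_distance == pytest.approx(brute_avg_path(net.graph))
            labels = detect_modules(net, min_size=1)
            comms = [
                {x for x, m in labels.items() if m == mid}
                for mid in sorted(set(labels.values()))
            ]
            assert t.modularity == pytest.approx(brute_modularity(net.graph, comms))
            pos = (signs > 0).sum()
            assert t.positive_pct == pytest.approx(
                round(100 * pos / len(signs), 2)
            )

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            network.topology(_net_from_edges([], n_nodes=3))


class TestEdgeSignSummary:
    def test_all_positive(self):
        assert network.edge_sign_summary(_net_from_edges([(0, 1)])) == (100.0, 0.0)

    def test_ten_positive_one_negative_split(self):
        """10 positive + 1 negative edge -> 90.91 / 9.09."""
        edges = [(0, i) for i in range(1, 11)] + [(11, 12)]
        signs = [1] * 10 + [-1]
        assert network.edge_sign_summary(_net_from_edges(edges, signs=signs)) == (
            90.91,
            9.09,
        )

    def test_even_split(self):
        net = _net_from_edges([(0, 1), (2, 3)], signs=[1, -1])
        assert network.edge_sign_summary(net) == (50.0, 50.0)


class TestRandomNull:
    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(12, 0.4, seed=3)
        net = _net_from_edges(list(g.edges), n_nodes=12)
        # contract check: rewire once by hand with the same routine
        r = net.graph.copy()
        nx.double_edge_swap(r, nswap=10 * r.number_of_edges(),
                            max_tries=1000 * r.number_of_edges(), seed=1)
        assert sorted(dict(r.degree).values()) == sorted(dict(net.graph.degree).values())

    def test_complete_graph_null_is_degenerate(self):
        g = nx.complete_graph(5)
        net = _net_from_edges(list(g.edges), n_nodes=5)
        null = network.random_null(net, n_rand=5, seed=0)
        for mean, sd in null.stats.values():
            assert sd == pytest.approx(0.0, abs=1e-12)

    def test_planted_modular_graph_beats_null_band(self):
        """Two planted cliques joined by one bridge: empirical M >> null."""
        g = nx.complete_graph(6)
        h = nx.relabel_nodes(nx.complete_graph(6), {i: i + 6 for i in range(6)})
        g = nx.compose(g, h)
        g.add_edge(0, 6)
        net = _net_from_edges(list(g.edges), n_nodes=12)
        emp = network.topology(net).modularity
        null = network.random_null(net, n_rand=30, seed=1)
        mean, sd = null.stats["modularity"]
        assert emp > mean + 2 * sd

    def test_er_graph_not_above_null_band(self):
        g = nx.gnp_random_graph(14, 0.5, seed=5)
        net = _net_from_edges(list(g.edges), n_nodes=14)
        emp = network.topology(net).modularity
        mean, sd = network.random_null(net, n_rand=30, seed=2).stats["modularity"]
        assert emp <= mean + 2 * sd


class TestModuleSimilarity:
    def test_fisher_matches_hypergeometric_tail(self):
        universe = set(range(40))
        a, b = set(range(12)), set(range(6, 18))
        overlap, p = network.fisher_module_overlap(a, b, universe)
        assert overlap == 6
        expected = hypergeom.sf(overlap - 1, 40, len(a), len(b))
        assert p == pytest.approx(expected, rel=1e-9)

    def test_identical_modules_similar_disjoint_not(self):
        part = {
            "G1": {**{n: 0 for n in range(10)}, **{n: 1 for n in range(20, 28)}},
            "G2": {**{n: 0 for n in range(10)}, **{n: 1 for n in range(30, 38)}},
        }
        rep = network.module_similarity(part)
        sim = rep.pairs.set_index(["module_a", "module_b"])
        identical = rep.pairs[
            (rep.pairs["module_a"] == 0) & (rep.pairs["module_b"] == 0)
        ].iloc[0]
        assert identical["similar"] and identical["p"] < 0.05
        disjoint = rep.pairs[
            (rep.pairs["module_a"] == 1) & (rep.pairs["module_b"] == 1)
        ].iloc[0]
        assert disjoint["p"] == pytest.approx(1.0)
        assert not disjoint["similar"]

    def test_retained_percentage_arithmetic(self):
        assert network.retained_percentage(3, 50) == 6.00
        with pytest.raises(ValueError):
            network.retained_percentage(5, 4)

    def test_clusters_by_transitive_closure(self):
        # shared 10-node module in three groups over a 40-node universe
        shared = {n: 0 for n in range(10)}
        background = {n: network.UNASSIGNED for n in range(100, 130)}
        part = {
            "G1": {**shared, **background},
            "G2": {**shared, **background},
            "G3": {**shared, **background},
        }
        for g_, extra in zip(part, ([50], [60], [70])):
            for n in extra:
                part[g_][n] = 0
        rep = network.module_similarity(part)
        assert len(rep.clusters) == 1
        assert len(rep.clusters[0]) == 3


class TestRmtThreshold:
    def test_fixed_mode_returns_configured_value(self):
        corr = pd.DataFrame(np.eye(10))
        assert network.rmt_threshold(corr, scan=False, fixed=0.995) == 0.995

    def test_identity_matrix_degenerate_returns_fixed(self):
        corr = pd.DataFrame(np.eye(40))
        out = network.rmt_threshold(corr, scan=True, fixed=0.995)
        assert out == 0.995

    def test_block_structure_scan_separates_blocks_from_background(self):
        """Planted near-1 blocks over weak background: scan picks a cutoff
        above the background correlation scale and below the block scale."""
        rng = np.random.default_rng(0)
        n_blocks, size = 6, 8
        n = n_blocks * size
        base = rng.normal(0, 0.05, size=(n, n))
        corr = (base + base.T) / 2
        for b in range(n_blocks):
            sl = slice(b * size, (b + 1) * size)
            corr[sl, sl] = 0.95 + rng.normal(0, 0.01, size=(size, size))
            corr[sl, sl] = (corr[sl, sl] + corr[sl, sl].T) / 2
        np.fill_diagonal(corr, 1.0)
        out = network.rmt_threshold(
            pd.DataFrame(corr), candidate_grid=np.arange(0.2, 0.9, 0.1), scan=True
        )
        assert 0.2 <= out < 0.9

    def test_asymmetric_rejected(self):
        bad = pd.DataFrame(np.arange(9.0).reshape(3, 3))
        with pytest.raises(ValueError):
            network.rmt_threshold(bad)


class TestGraphIO:
    def test_edge_tsv_roundtrip(self, tmp_path):
        corr = pd.DataFrame(
            [[1.0, 0.9, -0.8], [0.9, 1.0, 0.1], [-0.8, 0.1, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        net = from_correlation(corr, 0.7)
        path = tmp_path / "edges.tsv"
        net.to_edge_tsv(path)
        back = SignedNetwork.from_edge_tsv(path, 0.7)
        assert set(back.graph.edges) == set(net.graph.edges)
        assert back.graph["a"]["c"]["sign"] == -1
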