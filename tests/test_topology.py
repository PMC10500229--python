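"""Centrality conventions, pivotal screening, power-law fitting."""

import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fercerna import (
    build_network,
    centrality_table,
    extract_subnetwork,
    fit_power_law,
    fit_power_law_histogram,
    intersect_top_ranked,
    pivotal_lncrnas,
    top_k_with_ties,
)
from fercerna.cerna import CeRNANetwork, TRIAD_COLUMNS
from conftest import random_graph


def brute_force_betweenness(g):
    """Enumerate all shortest paths of every unordered pair explicitly."""
    out = {n: 0.0 for n in g.nodes}
    for s, t in itertools.combinations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for v in path[1:-1]:
                out[v] += 1.0 / len(paths)
    return out


def brute_force_harmonic(g):
    out = {}
    for n in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, n)
        out[n] = sum(1.0 / d for m, d in lengths.items() if m != n)
    return out


def as_network(g):
    """Wrap a bare graph for centrality (triads unused there)."""
    for n in g.nodes:
        g.nodes[n].setdefault("node_class", "mRNA")
        g.nodes[n].setdefault("direction", "up")
        g.nodes[n].setdefault("log2fc", 1.0)
    return CeRNANetwork(graph=g, triads=pd.DataFrame(columns=TRIAD_COLUMNS))


def triads(*rows):
    return pd.DataFrame(list(rows), columns=TRIAD_COLUMNS)


def test_path_graph_betweenness_closed_form():
    table = centrality_table(as_network(nx.path_graph(3))).set_index("node")
    assert table.loc[1, "betweenness"] == 1.0
    assert table.loc[0, "betweenness"] == 0.0


def test_star_graph_closed_forms():
    table = centrality_table(as_network(nx.star_graph(4))).set_index("node")
    assert table.loc[0, "degree"] == 4
    assert table.loc[0, "betweenness"] == 6.0  # all C(4,2) leaf pairs
    assert table.loc[0, "closeness"] == 4.0
    assert table.loc[1, "closeness"] == pytest.approx(2.5)  # 1 + 3/2


def test_classic_closeness_variant():
    table = centrality_table(as_network(nx.path_graph(3)), closeness="classic")
    by_node = table.set_index("node")["closeness"]
    assert by_node[1] == pytest.approx(1.0)  # (n-1)/sum(d) = 2/2
    assert by_node[0] == pytest.approx(2 / 3)


def test_betweenness_and_closeness_match_bruteforce_on_random_graphs():
    rng = np.random.default_rng(42)
    for _ in range(100):
        g = random_graph(rng, max_nodes=12)
        table = centrality_table(as_network(g)).set_index("node")
        bf_b = brute_force_betweenness(g)
        bf_h = brute_force_harmonic(g)
        for n in g.nodes:
            assert table.loc[n, "betweenness"] == pytest.approx(bf_b[n], abs=1e-9)
            assert table.loc[n, "closeness"] == pytest.approx(bf_h[n], abs=1e-9)
            assert table.loc[n, "degree"] == g.degree(n)


def test_tree_betweenness_equals_pair_counting_closed_form():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(4, 31))
        tree = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
        table = centrality_table(as_network(tree)).set_index("node")
        for v in tree.nodes:
            comps = [
                len(c) for c in nx.connected_components(tree.subgraph(set(tree) - {v}))
            ]
            expected = (n - 1) * (n - 2) / 2 - sum(s * (s - 1) / 2 for s in comps)
            assert table.loc[v, "betweenness"] == pytest.approx(expected)


def test_degree_sum_equals_twice_edge_count(default_analysis):
    net = default_analysis.network
    assert sum(d for _, d in net.graph.degree()) == 2 * net.graph.number_of_edges()


def test_harmonic_closeness_never_decreases_when_adding_an_edge():
    rng = np.random.default_rng(5)
    for _ in range(20):
        g = random_graph(rng, max_nodes=10)
        non_edges = list(nx.non_edges(g))
        if not non_edges:
            continue
        before = brute_force_harmonic(g)
        u, v = non_edges[int(rng.integers(len(non_edges)))]
        g.add_edge(u, v)
        after = brute_force_harmonic(g)
        assert all(after[n] >= before[n] - 1e-12 for n in g.nodes)


class TestPivotalScreen:
    def table(self, rows):
        return pd.DataFrame(
            rows, columns=["node", "node_class", "degree", "betweenness", "closeness"]
        )

    def test_single_leader_with_k_one(self):
        t = self.table(
            [("L1", "lncRNA", 5, 9.0, 9.0), ("L2", "lncRNA", 1, 1.0, 1.0),
             ("M1", "miRNA", 9, 99.0, 99.0)]
        )
        assert pivotal_lncrnas(t, k=1) == {"L1"}

    def test_ties_at_kth_value_are_included(self):
        values = {"a": 3.0, "b": 2.0, "c": 2.0, "d": 1.0}
        assert top_k_with_ties(values, 2) == {"a", "b", "c"}

    def test_row_permutation_invariance_against_bruteforce(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(3, 12))
            rows = [
                (f"L{i}", "lncRNA", int(rng.integers(1, 6)),
                 float(rng.integers(0, 50)), float(rng.integers(1, 20)))
                for i in range(n)
            ]
            t = self.table(rows)
            k = int(rng.integers(1, 6))
            # independent reimplementation: sort + cutoff + intersect
            expected = None
            for col in (2, 3, 4):
                vals = sorted((r[col] for r in rows), reverse=True)
                cutoff = vals[min(k, n) - 1]
                top = {r[0] for r in rows if r[col] >= cutoff}
                expected = top if expected is None else expected & top
            assert pivotal_lncrnas(t, k=k) == expected
            shuffled = t.sample(frac=1, random_state=int(rng.integers(2**31)))
            assert pivotal_lncrnas(shuffled, k=k) == expected

    def test_fewer_lncrnas_than_k_uses_all_with_warning(self):
        t = self.table([("L1", "lncRNA", 3, 1.0, 1.0)])
        with pytest.warns(UserWarning):
            assert pivotal_lncrnas(t, k=5) == {"L1"}


class TestPowerLaw:
    def test_two_point_histogram_is_exactly_collinear(self):
        fit = fit_power_law_histogram([1, 5], [20, 3])
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_power_law_histogram_recovers_coefficients(self):
        ks = np.arange(1, 11)
        ns = 24.024 * ks ** -0.976
        fit = fit_power_law_histogram(ks, ns)
        assert fit.a == pytest.approx(24.024, rel=1e-9)
        assert fit.b == pytest.approx(-0.976, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_histogram_matches_closed_form_ols(self):
        rng = np.random.default_rng(8)
        ks = np.arange(1, 13)
        ns = 30.0 * ks ** -1.2 * 2 ** rng.normal(0, 0.1, size=ks.size)
        fit = fit_power_law_histogram(ks, ns)
        x, y = np.log10(ks), np.log10(ns)
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        assert fit.b == pytest.approx(slope, rel=1e-10)
        assert fit.a == pytest.approx(10**intercept, rel=1e-10)

    def test_single_degree_value_fails(self):
        net = as_network(nx.path_graph(2))  # both nodes have degree 1
        with pytest.raises(ValueError):
            fit_power_law(net)
        with pytest.raises(ValueError):
            fit_power_law_histogram([3], [10])


class TestSubnetwork:
    def test_all_lncrnas_pivotal_is_identity(self, default_analysis):
        net = default_analysis.network
        all_lncs = {
            n for n, d in net.graph.nodes(data=True) if d["node_class"] == "lncRNA"
        }
        sub = extract_subnetwork(net, all_lncs)
        assert nx.utils.graphs_equal(sub.graph, net.graph)

    def test_one_pivotal_lncrna_in_two_triad_network(self):
        net = build_network(
            triads(
                ("L1", "M1", "G1", "up", "down", "up"),
                ("L2", "M2", "G2", "up", "down", "up"),
            )
        )
        sub = extract_subnetwork(net, {"L1"})
        assert sub.graph.number_of_nodes() == 3
        assert sub.graph.number_of_edges() == 2

    def test_subnetwork_nodes_equal_union_of_pivotal_triads(self, default_analysis):
        res = default_analysis
        expected = set(
            res.triads[res.triads["lncrna"].isin(res.pivotal)][
                ["lncrna", "mirna", "mrna"]
            ].values.ravel()
        )
        assert set(res.subnetwork.graph.nodes) == expected

    def test_empty_pivotal_warns_and_stray_id_raises(self, default_analysis):
        net = default_analysis.network
        with pytest.warns(UserWarning):
            sub = extract_subnetwork(net, set())
        assert sub.graph.number_of_nodes() == 0
        with pytest.raises(ValueError):
            extract_subnetwork(net, {"NOT_A_NODE"})
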