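"""Prevalence filtering, correlation edges with BH adjustment, and network
topology (clustering coefficient, greedy-CNM modularity)."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from biogeo import network


class TestPrevalenceFilter:
    def test_half_prevalence_removed_strictly(self):
        table = pd.DataFrame({
            "half": [1] * 5 + [0] * 5,       # 5/10 -> removed (strict >)
            "six": [1] * 6 + [0] * 4,        # 6/10 -> kept
            "all": [2] * 10,
        }, index=[f"s{i}" for i in range(10)])
        out = network.prevalence_filter(table)
        assert list(out.columns) == ["six", "all"]

    def test_ubiquitous_table_unchanged(self, rng):
        table = pd.DataFrame(rng.integers(1, 9, size=(6, 4)),
                             index=[f"s{i}" for i in range(6)],
                             columns=list("abcd"))
        pd.testing.assert_frame_equal(network.prevalence_filter(table), table)


class TestCorrelationEdges:
    def test_identical_otus_form_positive_edge(self, rng):
        x = rng.uniform(size=12)
        table = pd.DataFrame({"a": x, "b": x, "c": rng.uniform(size=12)},
                             index=[f"s{i}" for i in range(12)])
        edges = network.correlation_edges(table)
        pair = edges[(edges.otu_a == "a") & (edges.otu_b == "b")]
        assert len(pair) == 1
        assert pair.iloc[0].rho == pytest.approx(1.0)
        assert pair.iloc[0].sign == "positive"

    def test_antitone_otus_form_negative_edge(self, rng):
        x = rng.uniform(size=12)
        table = pd.DataFrame({"a": x, "b": -(x**3)},
                             index=[f"s{i}" for i in range(12)])
        edges = network.correlation_edges(table)
        assert edges.iloc[0].rho == pytest.approx(-1.0)
        assert edges.iloc[0].sign == "negative"

    def test_constant_otu_skipped_with_warning(self, rng):
        table = pd.DataFrame({"a": rng.uniform(size=10), "flat": np.ones(10),
                              "b": rng.uniform(size=10)},
                             index=[f"s{i}" for i in range(10)])
        with pytest.warns(UserWarning, match="constant"):
            edges = network.correlation_edges(table)
        assert not ((edges.otu_a == "flat") | (edges.otu_b == "flat")).any()

    def test_bh_adjustment_by_hand(self):
        # step-up BH: raw (0.01, 0.02, 0.04) -> adjusted (0.03, 0.03, 0.04)
        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04])
        # all-equal raw p-values stay equal after adjustment
        adj = multipletests([0.02, 0.02, 0.02, 0.02], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, 0.02)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_bh_monotone_and_never_below_raw(self, pvals):
        adj = multipletests(pvals, method="fdr_bh")[1]
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= np.asarray(pvals) - 1e-12).all()


def modularity_brute_force(g: nx.Graph) -> float:
    """Best Newman Q over all set partitions (Bell-number enumeration)."""
    nodes = list(g.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [head]] + part[i + 1:]
            yield part + [[head]]

    best = -1.0
    for part in partitions(nodes):
        q = nx.community.modularity(g, [set(c) for c in part], weight=None)
        best = max(best, q)
    return best


class TestTopology:
    def _net(self, edges):
        df = pd.DataFrame(
            [{"otu_a": a, "otu_b": b, "rho": 0.9, "p_raw": 1e-4,
              "p_adj": 1e-3, "sign": "positive"} for a, b in edges],
            columns=network.EDGE_COLUMNS)
        return network.build_network(df)

    def test_single_edge_counts(self):
        topo = self._net([("a", "b")]).topology
        assert (topo.n_nodes, topo.n_links) == (2, 1)
        assert topo.avgK == pytest.approx(1.0)

    def test_triangle(self):
        topo = self._net([("a", "b"), ("b", "c"), ("a", "c")]).topology
        assert topo.avgK == pytest.approx(2.0)
        assert topo.avgCC == pytest.approx(1.0)

    def test_two_disconnected_triangles_modularity_half(self):
        net = self._net([("a", "b"), ("b", "c"), ("a", "c"),
                         ("x", "y"), ("y", "z"), ("x", "z")])
        # direct Q = sum(e_ii - a_i^2) for the two-component partition
        assert net.topology.modularity == pytest.approx(0.5)

    def test_complete_graph_modularity_nonnegative_small(self):
        edges = list(itertools.combinations("abcd", 2))
        topo = self._net(edges).topology
        assert topo.avgCC == pytest.approx(1.0)
        assert 0 <= topo.modularity <= 0.05

    def test_greedy_close_to_exhaustive_on_small_graphs(self, rng):
        for trial in range(6):
            g = nx.gnp_random_graph(7, 0.4, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            greedy = network.modularity_cnm(g)
            exact = modularity_brute_force(g)
            assert greedy <= exact + 1e-12
            assert greedy >= exact - 0.05

    def test_modularity_within_theoretical_bounds(self, rng):
        for _ in range(5):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            q = network.modularity_cnm(g)
            assert -0.5 <= q <= 1.0

    def test_avgk_identity_on_random_graphs(self, rng):
        for _ in range(5):
            g = nx.gnp_random_graph(10, 0.4, seed=int(rng.integers(1 << 30)))
            topo = network.topology(g)
            if topo.n_nodes:
                assert topo.avgK == pytest.approx(2 * topo.n_links / topo.n_nodes)

    def test_empty_network_zeroed_and_flagged(self):
        net = network.build_network(pd.DataFrame(columns=network.EDGE_COLUMNS))
        assert net.topology.empty
        assert net.topology.n_nodes == 0
        assert net.topology.modularity == 0.0

    def test_metrics_invariant_to_relabeling(self, rng):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c")]
        t1 = self._net(edges).topology
        relabeled = [(x.upper(), y.upper()) for x, y in edges]
        t2 = self._net(relabeled).topology
        assert (t1.n_nodes, t1.n_links, t1.avgK, t1.avgCC, t1.modularity) == (
            t2.n_nodes, t2.n_links, t2.avgK, t2.avgCC, t2.modularity)

    def test_all_positive_edges_fraction_one(self):
        topo = self._net([("a", "b"), ("b", "c")]).topology
        assert topo.frac_positive == 1.0


class TestPlantedBlocks:
    def test_blocks_recovered_as_connected_components(self, small_config, small_meta):
        from biogeo import synth

        table = synth.generate_community(small_config, small_meta, "bacteria")
        filtered = network.prevalence_filter(table)
        edges = network.correlation_edges(filtered)
        g = network.build_network(edges).graph
        comps = [set(c) for c in nx.connected_components(g)]
        truth = synth.planted_truth(small_config, "bacteria")
        for block in truth.blocks:
            matches = [c for c in comps if set(block) & c]
            assert len(matches) == 1
            assert matches[0] == set(block)

    def test_region_networks_cover_all_regions(self, small_config, small_meta):
        from biogeo import synth

        table = synth.generate_community(small_config, small_meta, "bacteria")
        nets = network.region_networks(table, small_meta["region"])
        assert set(nets) == set(small_meta["region"].unique())
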