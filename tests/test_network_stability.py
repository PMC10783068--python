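import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hadal.io_formats import AbundanceTable
from hadal.network_stability import (
    CoNetwork,
    betweenness,
    build_network,
    compare_zones,
    correlation_matrix,
    fragmentation,
    fragmentation_series,
    rank_hubs,
    robustness,
    rmt_threshold,
    topology,
)

from .oracles import betweenness_bfs, fragmentation_components


def as_net(graph, **kw):
    defaults = dict(threshold=0.8, mode="fixed")
    defaults.update(kw)
    return CoNetwork(graph, **defaults)


def table_from_matrix(m, taxa=None):
    m = np.asarray(m)
    taxa = taxa or [f"t{i}" for i in range(m.shape[0])]
    return AbundanceTable(
        pd.DataFrame(m, index=taxa, columns=[f"s{j}" for j in range(m.shape[1])])
    )


class TestBuildNetwork:
    def test_perfect_correlation_single_edge(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 200, size=8)
        rows = [base, base * 3]  # r = 1 after log-relative transform
        for _ in range(10):
            rows.append(rng.integers(10, 200, size=8))
        t = table_from_matrix(np.array(rows))
        net = build_network(t, threshold=0.95, min_prevalence=1)
        assert net.n_edges == 1
        (u, v, data), = net.graph.edges(data=True)
        assert {u, v} == {"t0", "t1"}
        assert data["sign"] == "+"

    def test_anticorrelated_pair_gets_negative_sign(self):
        up = np.array([10, 20, 40, 80, 160, 320, 640, 1000])
        down = up[::-1].copy()
        rng = np.random.default_rng(1)
        rows = [up, down] + [rng.integers(10, 500, size=8) for _ in range(10)]
        t = table_from_matrix(np.array(rows))
        net = build_network(t, threshold=0.95, min_prevalence=1)
        assert net.graph.has_edge("t0", "t1")
        assert net.graph.edges["t0", "t1"]["sign"] == "-"
        glob, _ = topology(net)
        sub_edges = [
            d["sign"] for _, _, d in net.graph.edges(data=True)
        ]
        assert glob["negative_link_ratio"] == pytest.approx(
            sub_edges.count("-") / len(sub_edges)
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_rmt_rejects_iid_noise(self, seed):
        # with 20 samples the null Pearson sd is 1/sqrt(19) ~ 0.23 and
        # the GOE -> Poisson transition coincides with the density at
        # which the thresholded graph fragments (~1% of pairs); the
        # selected cutoff must pin the density at that noise floor,
        # orders of magnitude below the 36% a naive p < 0.05 edge
        # screen would keep
        rng = np.random.default_rng(seed)
        t = table_from_matrix(rng.poisson(60, size=(200, 20)) + 1)
        net = build_network(t, threshold="rmt", min_prevalence=5)
        density = net.n_edges / (200 * 199 / 2)
        assert net.threshold >= 0.5
        assert density < 0.015

    def test_correlation_matrix_properties(self):
        rng = np.random.default_rng(2)
        t = table_from_matrix(rng.integers(1, 500, size=(30, 10)))
        from hadal.table_ops import log_relative

        corr = correlation_matrix(log_relative(t))
        c = corr.to_numpy()
        assert np.allclose(c, c.T, atol=1e-12)
        assert np.allclose(np.diag(c), 1.0, atol=1e-12)

    def test_edge_set_invariant_to_row_order(self):
        rng = np.random.default_rng(3)
        m = rng.integers(1, 500, size=(25, 10))
        t1 = table_from_matrix(m)
        order = rng.permutation(25)
        t2 = AbundanceTable(t1.counts.iloc[order])
        n1 = build_network(t1, threshold=0.7, min_prevalence=1)
        n2 = build_network(t2, threshold=0.7, min_prevalence=1)
        e1 = {frozenset(e) for e in n1.graph.edges}
        e2 = {frozenset(e) for e in n2.graph.edges}
        assert e1 == e2

    def test_too_few_samples_rejected(self):
        t = table_from_matrix(np.ones((12, 2), dtype=int))
        with pytest.raises(ValueError):
            build_network(t, threshold=0.8)


class TestTopology:
    def test_average_degree_equals_two_e_over_n(self):
        g = nx.gnm_random_graph(50, 160, seed=1)
        glob, _ = topology(as_net(g))
        assert glob["average_degree"] == pytest.approx(2 * 160 / 50)
        # recompute from the graph's own edge list
        assert glob["average_degree"] == pytest.approx(
            sum(d for _, d in g.degree) / 50
        )

    def test_triangle(self):
        g = nx.complete_graph(3)
        glob, nodes = topology(as_net(g))
        assert (nodes["clustering"] == 1.0).all()
        assert (nodes["betweenness"] == 0.0).all()

    def test_two_disconnected_cliques_modularity_half(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        glob, _ = topology(as_net(g))
        assert glob["n_components"] == 2
        assert glob["modularity"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_betweenness_matches_bfs_oracle(self, seed):
        g = nx.gnm_random_graph(15, 30, seed=seed)
        ours = betweenness(g)
        adj = {v: sorted(g.neighbors(v)) for v in g.nodes}
        expected = betweenness_bfs(adj)
        for v in g.nodes:
            assert ours[v] == pytest.approx(expected[v], abs=1e-8)


class TestRankHubs:
    def test_star_center_by_degree(self):
        g = nx.star_graph(6)
        net = as_net(g)
        assert rank_hubs(net, k=1, criterion="degree") == [0]

    def test_path_middle_by_betweenness(self):
        g = nx.path_graph(3)
        assert rank_hubs(as_net(g), k=1, criterion="betweenness") == [1]

    def test_hand_sorted_degrees(self):
        g = nx.Graph()
        # node i gets degree i by wiring to i distinct partners
        for i in range(1, 7):
            for j in range(i):
                g.add_edge(f"n{i}", f"p{i}_{j}")
        ranking = rank_hubs(as_net(g), k=6, criterion="degree")
        assert ranking == [f"n{i}" for i in range(6, 0, -1)]

    def test_abundance_criterion_and_overflow_warning(self):
        g = nx.path_graph(3)
        for i, v in enumerate(g.nodes):
            g.nodes[v]["mean_abundance"] = float(i)
        assert rank_hubs(as_net(g), k=1, criterion="abundance") == [2]
        assert len(rank_hubs(as_net(g), k=10, criterion="degree")) == 3


class TestRobustness:
    def test_complete_graph_half_removal(self):
        net = as_net(nx.complete_graph(10))
        for mode in ("random", "targeted"):
            res = robustness(net, 0.5, mode, reps=5, seed=0)
            assert res.robustness_mean == pytest.approx(0.5)

    def test_tiny_fraction_equals_intact_nonisolated_share(self):
        g = nx.complete_graph(10)
        g.add_nodes_from(["iso1", "iso2"])  # two isolated taxa
        net = as_net(g)
        res = robustness(net, fraction=1e-9, mode="random", reps=3, seed=1)
        assert res.robustness_mean == pytest.approx(10 / 12)

    def test_star_center_targeted_removal_isolates_everything(self):
        g = nx.star_graph(9)  # 10 nodes; floor(0.1 * 10) = 1 removal
        res = robustness(as_net(g), fraction=0.1, mode="targeted", seed=0)
        assert res.robustness_mean == 0.0
        assert res.removal_order == [0]

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            robustness(as_net(nx.complete_graph(4)), fraction=1.5)


class TestFragmentation:
    def test_connected_graph_is_zero(self):
        assert fragmentation(nx.complete_graph(6)) == 0.0

    def test_fully_isolated_is_one(self):
        g = nx.empty_graph(5)
        assert fragmentation(g) == 1.0

    def test_component_sizes_three_two(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("d", "e")])
        assert fragmentation(g) == pytest.approx(0.6)
        adj = {v: list(g.neighbors(v)) for v in g.nodes}
        assert fragmentation(g) == pytest.approx(fragmentation_components(adj))

    def test_series_is_nondecreasing_on_structured_network(self, small_niche):
        # normalizing by the remaining node count N' allows hairline
        # decreases when a node leaves an already-small component, so
        # the monotonicity contract carries a 1e-3 tolerance here; the
        # trend over the full removal sequence must still be upward
        table, _ = small_niche
        net = build_network(table, threshold=0.8, min_prevalence=4)
        res = fragmentation_series(net, k=10)
        assert res.fragmentation[0] >= 0.0
        assert (np.diff(res.fragmentation) >= -1e-3).all()
        assert res.fragmentation[-1] >= res.fragmentation[0]
        assert len(res.removal_order) == 10

    def test_needs_more_nodes_than_removals(self):
        with pytest.raises(ValueError):
            fragmentation_series(as_net(nx.complete_graph(5)), k=10)


class TestCompareZones:
    def test_identical_networks_have_zero_differences(self):
        g = nx.gnm_random_graph(30, 80, seed=2)
        report = compare_zones(as_net(g), as_net(g.copy()), reps=20, seed=0)
        a, b = report["UBW"], report["HW"]
        for key in ("n_nodes", "n_edges", "average_degree", "robustness_targeted"):
            assert a[key] == b[key]
        assert "negative_link_ratio" in a and "negative_link_ratio" in b
        assert report["robustness_test"]["p_value"] > 0.01

    def test_clique_survives_targeting_better_than_path(self):
        n = 12
        clique = as_net(nx.complete_graph(n))
        path = as_net(nx.path_graph(n))
        rc = robustness(clique, 0.5, "targeted", seed=0).robustness_mean
        rp = robustness(path, 0.5, "targeted", seed=0).robustness_mean
        assert rc >= rp

    def test_mismatched_settings_rejected(self):
        g = nx.complete_graph(5)
        with pytest.raises(ValueError):
            compare_zones(as_net(g), as_net(g, threshold=0.6), reps=5)
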