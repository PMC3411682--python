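"""Global indicators and centrality measures against independent oracles."""

import math

import numpy as np
import pytest

import oracles
from netcascade import (Network, betweenness_centrality, closeness_centrality,
                        connected_components, eigenvector_centrality,
                        metrics_table, node_metrics, shortest_path_lengths,
                        summarize)
from netcascade.fixtures import complete, erdos_renyi, path, star
from netcascade.topology import sorted_listing


def random_net(n, p, seed):
    rng = np.random.default_rng(seed)
    labels = [f"v{i:02d}" for i in range(n)]
    edges = [
        (labels[i], labels[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return Network.from_edges(edges, extra_nodes=labels), labels, edges


class TestComponents:
    def test_triangle_single_component(self, triangle):
        assert set(connected_components(triangle).values()) == {1}

    def test_two_disjoint_edges(self):
        net = Network.from_edges([("A", "B"), ("C", "D")])
        comp = connected_components(net)
        assert comp["A"] == comp["B"] != comp["C"] == comp["D"]

    def test_ids_ordered_by_size_then_label(self):
        net = Network.from_edges([("x", "y"), ("a", "b"), ("p", "q"), ("q", "r")])
        comp = connected_components(net)
        assert comp["p"] == 1  # largest component first
        assert comp["a"] == 2  # size tie broken by smallest member label
        assert comp["x"] == 3

    def test_matches_union_find_oracle_on_sparse_er(self):
        net, labels, edges = random_net(200, 0.005, seed=11)
        assert connected_components(net) == oracles.union_find_components(
            labels, edges
        )


class TestDistances:
    def test_path_distances(self, path_abc):
        assert shortest_path_lengths(path_abc, "A") == {"A": 0, "B": 1, "C": 2}

    def test_unreachable_is_none(self):
        net = Network.from_edges([("A", "B")], extra_nodes=["C"])
        assert shortest_path_lengths(net, "A")["C"] is None

    def test_unknown_source_raises(self, triangle):
        with pytest.raises(KeyError):
            shortest_path_lengths(triangle, "Z")

    def test_matches_floyd_warshall_rows(self):
        net, labels, edges = random_net(30, 0.1, seed=5)
        dist = oracles.floyd_warshall(oracles.adjacency(labels, edges))
        for i, src in enumerate(labels):
            got = shortest_path_lengths(net, src)
            for j, lab in enumerate(labels):
                expect = None if not np.isfinite(dist[i, j]) else int(dist[i, j])
                assert got[lab] == expect


class TestSummary:
    def test_triangle(self, triangle):
        s = summarize(triangle)
        assert (s.size, s.density, s.avg_degree) == (3, 1.0, 2.0)
        assert s.avg_path_length == 1.0
        assert s.n_components == 1

    def test_star_k14(self):
        # 20 ordered pairs: 8 at distance 1 (hub-leaf both ways), 12 at 2
        s = summarize(star(4))
        assert s.density == pytest.approx(0.4)
        assert s.avg_degree == pytest.approx(1.6)
        assert s.avg_path_length == pytest.approx(1.6)

    def test_food_web_average_degree(self):
        net = Network.from_edges(
            [(f"n{i:03d}", f"n{(i + 1) % 219:03d}") for i in range(219)]
            + [(f"n{i:03d}", f"n{(i + k) % 219:03d}")
               for k in (2, 3) for i in range(219)]
            + [(f"n{i:03d}", f"n{(i + 5) % 219:03d}") for i in range(155)]
        )
        assert (net.size, net.edge_count) == (219, 812)
        assert round(summarize(net).avg_degree, 1) == 7.4

    def test_density_avg_degree_identity(self):
        for seed in range(5):
            net = erdos_renyi(40, 0.1, seed=seed)
            s = summarize(net)
            assert s.density == pytest.approx(s.avg_degree / (s.size - 1))

    def test_no_connected_pairs_gives_nan(self):
        net = Network(nodes=frozenset({"A", "B"}), edges=frozenset())
        assert math.isnan(summarize(net).avg_path_length)


class TestBetweenness:
    def test_path_center(self, path_abc):
        assert betweenness_centrality(path_abc) == {"A": 0.0, "B": 1.0, "C": 0.0}

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_star_hub_is_leaf_pair_count(self, n):
        btw = betweenness_centrality(star(n))
        assert btw["hub"] == pytest.approx(n * (n - 1) / 2)

    def test_complete_graph_all_zero(self):
        assert all(v == 0 for v in betweenness_centrality(complete(4)).values())


class TestCloseness:
    def test_star_hub(self):
        assert closeness_centrality(star(3))["hub"] == pytest.approx(1.0)

    def test_substitution_rule_for_unreachable(self):
        net = Network.from_edges([("A", "B")], extra_nodes=["C"])
        clo = closeness_centrality(net)
        assert clo["A"] == pytest.approx(2 / (1 + 3))  # |V|=3 substituted for A-C
        assert clo["C"] == pytest.approx(1 / 3)  # isolated node: 1/|V|

    def test_path_values(self, path_abc):
        clo = closeness_centrality(path_abc)
        assert clo["B"] == pytest.approx(1.0)
        assert clo["A"] == pytest.approx(2 / 3)

    def test_single_node_undefined(self):
        net = Network(nodes=frozenset({"A"}), edges=frozenset())
        with pytest.raises(ValueError, match="undefined"):
            closeness_centrality(net)


class TestEigenvector:
    def test_complete_graph_symmetry(self):
        assert eigenvector_centrality(complete(3)) == pytest.approx(
            {n: 1.0 for n in complete(3).nodes}
        )

    @pytest.mark.parametrize("n", [2, 3, 5, 10])
    def test_star_leaf_hub_ratio(self, n):
        ev = eigenvector_centrality(star(n))
        assert ev["hub"] == pytest.approx(1.0)
        for leaf, val in ev.items():
            if leaf != "hub":
                assert val == pytest.approx(1 / math.sqrt(n), abs=1e-9)

    def test_path_matches_eigendecomposition(self, path_abc):
        ev = eigenvector_centrality(path_abc)
        assert ev["B"] == pytest.approx(1.0)
        assert ev["A"] == pytest.approx(1 / math.sqrt(2), abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_eigh_oracle_on_random_graphs(self, seed):
        net, labels, edges = random_net(15, 0.3, seed=seed)
        if net.edge_count == 0:
            pytest.skip("degenerate draw")
        ev = eigenvector_centrality(net)
        expect = oracles.brute_eigenvector(oracles.adjacency(labels, edges))
        for i, lab in enumerate(labels):
            assert ev[lab] == pytest.approx(expect[i], abs=1e-6)

    def test_rayleigh_quotient_residual(self):
        net, labels, edges = random_net(20, 0.2, seed=9)
        ev = eigenvector_centrality(net, tol=1e-12)
        a = oracles.adjacency(labels, edges)
        x = np.array([ev[lab] for lab in labels])
        lam = x @ a @ x / (x @ x)
        assert np.abs(a @ x - lam * x).max() < 1e-6 * lam

    def test_requires_an_edge(self):
        net = Network(nodes=frozenset({"A", "B"}), edges=frozenset())
        with pytest.raises(ValueError, match="at least one edge"):
            eigenvector_centrality(net)

    def test_disconnected_localizes_on_dominant_component(self):
        # triangle (spectral radius 2) beats a single edge (radius 1)
        net = Network.from_edges(
            [("A", "B"), ("B", "C"), ("A", "C"), ("X", "Y")]
        )
        ev = eigenvector_centrality(net)
        assert ev["A"] == pytest.approx(1.0)
        assert ev["X"] < 1e-6


class TestNodeMetricsListings:
    def test_path_degree_listing(self, path_abc):
        deg = {n: m.degree for n, m in node_metrics(path_abc).items()}
        assert sorted_listing(deg) == [("B", 2), ("A", 1), ("C", 1)]

    def test_star_hub_tops_every_listing(self):
        net = star(5)
        metrics = node_metrics(net)
        for attr in ("degree", "betweenness", "closeness", "eigenvector"):
            listing = sorted_listing({n: getattr(m, attr) for n, m in metrics.items()})
            assert listing[0][0] == "hub"

    def test_complete_graph_ties_lexicographic(self):
        net = complete(4)
        deg = {n: m.degree for n, m in node_metrics(net).items()}
        assert [n for n, _ in sorted_listing(deg)] == sorted(net.nodes)

    def test_metrics_table_columns(self, triangle):
        df = metrics_table(triangle)
        assert list(df.columns) == [
            "node", "degree", "betweenness", "closeness", "eigenvector",
            "component_id",
        ]
        assert (df["component_id"] == 1).all()


class TestPermutationEquivariance:
    def test_relabeling_permutes_all_metrics(self):
        net, labels, edges = random_net(12, 0.3, seed=4)
        mapping = {lab: f"z{ord(lab[1]) * 7 % 97:02d}{lab}" for lab in labels}
        relabeled = Network.from_edges(
            [(mapping[u], mapping[v]) for u, v in edges],
            extra_nodes=[mapping[l] for l in labels],
        )
        for fn in (betweenness_centrality, closeness_centrality):
            orig = fn(net)
            perm = fn(relabeled)
            for lab in labels:
                assert perm[mapping[lab]] == pytest.approx(orig[lab])
        s1, s2 = summarize(net), summarize(relabeled)
        assert s1 == s2
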