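import math

import networkx as nx
import numpy as np
import pytest

from metanets.habitat_network import (
    DistanceMatrix,
    build_network,
    component_path_stats,
    components,
    least_cost_distance,
    network_diameter,
    pairwise_edge_distance,
)
from metanets.landscape_io import GridTransform, HabitatMask, label_patches

from conftest import square_layer


def abc_network(theta, dab=400.0, dbc=450.0, dac=850.0, extra_nodes=0):
    ids = ["A", "B", "C"] + [f"D{k}" for k in range(extra_nodes)]
    n = len(ids)
    d = np.zeros((n, n))
    d[0, 1] = d[1, 0] = dab
    d[1, 2] = d[2, 1] = dbc
    d[0, 2] = d[2, 0] = dac
    # distant isolates
    for k in range(3, n):
        d[k, :3] = d[:3, k] = 99_999.0
        for j in range(3, n):
            if j != k:
                d[k, j] = d[j, k] = 99_999.0
    return build_network(DistanceMatrix(patch_ids=ids, d=d), theta, 0)


def brute_force_components(adj):
    """Oracle: transitive closure by repeated boolean matrix multiplication."""
    n = adj.shape[0]
    reach = adj | np.eye(n, dtype=bool)
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            break
        reach = nxt
    comps = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = frozenset(np.flatnonzero(reach[i]).tolist())
        seen |= comp
        comps.append(comp)
    return set(comps)


class TestEdgeDistances:
    def test_axis_aligned_gap(self):
        layer = square_layer([(0, 0), (4, 0)])
        dm = pairwise_edge_distance(layer)
        assert dm.d[0, 1] == pytest.approx(3.0)

    def test_touching_patches_distance_zero(self):
        layer = square_layer([(0, 0), (1, 0)])
        dm = pairwise_edge_distance(layer)
        assert dm.d[0, 1] == 0.0

    def test_diagonal_corner_to_corner(self):
        layer = square_layer([(0, 0), (2, 2)])
        dm = pairwise_edge_distance(layer)
        assert dm.d[0, 1] == pytest.approx(math.sqrt(2.0))


class TestBuildNetwork:
    def test_threshold_application(self):
        net = abc_network(theta=500.0)
        assert set(map(frozenset, net.graph.edges)) == {
            frozenset({"A", "B"}), frozenset({"B", "C"})
        }

    def test_small_threshold_isolates_all(self):
        net = abc_network(theta=250.0)
        assert net.graph.number_of_edges() == 0
        assert all(net.graph.degree[n] == 0 for n in net.graph.nodes)

    def test_large_threshold_complete_graph(self):
        net = abc_network(theta=900.0)
        assert net.graph.number_of_edges() == 3

    def test_edge_rule_is_closed_inequality(self):
        net = abc_network(theta=400.0)
        assert net.graph.has_edge("A", "B")  # d == theta still links


class TestComponents:
    def test_stepping_stone_plus_isolate(self):
        net = abc_network(theta=500.0, extra_nodes=1)
        part = components(net)
        assert set(part.components) == {frozenset({"A", "B", "C"}),
                                        frozenset({"D0"})}

    def test_no_edges_all_singletons(self):
        ids = list("abcde")
        d = np.full((5, 5), 1e6)
        np.fill_diagonal(d, 0.0)
        part = components(build_network(DistanceMatrix(patch_ids=ids, d=d), 10.0, 0))
        assert len(part) == 5

    def test_matches_brute_force_closure_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n = int(rng.integers(2, 13))
            d = rng.uniform(0, 1000, (n, n))
            d = np.triu(d, 1)
            d = d + d.T
            theta = float(rng.uniform(100, 900))
            ids = [f"p{k}" for k in range(n)]
            part = components(build_network(DistanceMatrix(patch_ids=ids, d=d),
                                            theta, 0))
            got = {frozenset(int(p[1:]) for p in comp) for comp in part.components}
            adj = (d <= theta) & ~np.eye(n, dtype=bool)
            assert got == brute_force_components(adj)


class TestNetworkDiameter:
    def test_chain_mean_shortest_path(self):
        net = abc_network(theta=500.0)
        # pairs: AB 400, BC 450, AC via B 850 -> mean 566.667
        assert network_diameter(net, {"A", "B", "C"}) == pytest.approx(1700 / 3)

    def test_two_node_component(self):
        net = abc_network(theta=500.0)
        assert network_diameter(net, {"A", "B"}) == pytest.approx(400.0)

    def test_equal_weight_triangle(self):
        ids = ["a", "b", "c"]
        d = np.array([[0, 7.0, 7.0], [7.0, 0, 7.0], [7.0, 7.0, 0]])
        net = build_network(DistanceMatrix(patch_ids=ids, d=d), 10.0, 0)
        assert network_diameter(net, set(ids)) == pytest.approx(7.0)

    def test_singleton_flagged_missing(self):
        net = abc_network(theta=500.0)
        assert math.isnan(network_diameter(net, {"A"}))

    def test_disconnected_input_errors(self):
        net = abc_network(theta=500.0, extra_nodes=1)
        with pytest.raises(ValueError, match="not connected"):
            network_diameter(net, {"A", "D0"})

    def test_max_reported_alongside_mean(self):
        net = abc_network(theta=500.0)
        stats = component_path_stats(net, {"A", "B", "C"})
        assert stats.max == pytest.approx(850.0)
        assert stats.mean <= stats.max

    def test_edge_removal_never_decreases_mean_path(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = 7
            d = rng.uniform(10, 100, (n, n))
            d = np.triu(d, 1) + np.triu(d, 1).T
            ids = [f"p{k}" for k in range(n)]
            net = build_network(DistanceMatrix(patch_ids=ids, d=d), 200.0, 0)
            before = network_diameter(net, set(ids))
            edges = list(net.graph.edges)
            e = edges[int(rng.integers(len(edges)))]
            g2 = net.graph.copy()
            g2.remove_edge(*e)
            if not nx.is_connected(g2):
                continue
            net.graph = g2
            assert network_diameter(net, set(ids)) >= before - 1e-9


class TestCoarsening:
    def test_partition_coarsens_with_threshold(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(3, 15))
            d = rng.uniform(0, 2500, (n, n))
            d = np.triu(d, 1) + np.triu(d, 1).T
            ids = [f"p{k}" for k in range(n)]
            dm = DistanceMatrix(patch_ids=ids, d=d)
            prev = None
            for theta in (250.0, 500.0, 750.0, 1000.0, 2000.0):
                part = components(build_network(dm, theta, 0))
                if prev is not None:
                    assert len(part) <= len(prev)
                    for comp in prev:
                        assert any(comp <= big for big in part.components)
                prev = part.components


class TestLeastCost:
    def grid_layer(self, cells, shape=(40, 40), cell=10.0):
        grid = np.zeros(shape, dtype=np.uint8)
        for r, c in cells:
            grid[r, c] = 1
        t = GridTransform(x0=0.0, y0=shape[0] * cell, cell=cell)
        return label_patches(HabitatMask(grid=grid, transform=t, timestep_label=0))

    def test_straight_path_on_uniform_grid(self):
        layer = self.grid_layer([(5, 2), (5, 32)])
        d = least_cost_distance(1.0, layer, tuple(layer.ids))
        assert d == pytest.approx(300.0)

    def test_diagonal_metric(self):
        layer = self.grid_layer([(2, 2), (10, 10)])
        d = least_cost_distance(1.0, layer, tuple(layer.ids))
        assert d == pytest.approx(8 * 10.0 * math.sqrt(2.0))

    def test_patch_outside_grid_errors(self):
        layer = self.grid_layer([(5, 2), (5, 32)])
        small = np.ones((10, 10))
        with pytest.raises(ValueError, match="outside"):
            least_cost_distance(small, layer, tuple(layer.ids))

    def test_uniform_resistance_close_to_euclidean_between_extended_patches(self):
        # boundary-to-boundary comparison; discretisation offsets allowed on
        # top of the 8-neighbour anisotropy, hence the looser 12% bound
        rng = np.random.default_rng(6)
        grid = np.zeros((80, 80), dtype=np.uint8)
        grid[10:13, 10:13] = 1
        grid[60:63, 65:68] = 1
        t = GridTransform(x0=0.0, y0=800.0, cell=10.0)
        layer = label_patches(HabitatMask(grid=grid, transform=t, timestep_label=0))
        lc = least_cost_distance(1.0, layer, tuple(layer.ids))
        eu = pairwise_edge_distance(layer).d[0, 1]
        assert lc >= eu * 0.9
        assert lc <= eu * 1.12
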