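import networkx as nx
import numpy as np
import pytest

from beetlenet import (
    edge_centralities,
    node_centralities,
    whole_network_attributes,
)
from beetlenet.graph_metrics import MetricsError

from oracles import brute_force_betweenness


def test_complete_graph_closed_forms():
    a = whole_network_attributes(nx.complete_graph(5))
    assert a.clustering_coefficient == 1.0
    assert a.density == 1.0
    assert a.heterogeneity == 0.0
    assert a.centralization == pytest.approx(0.0)
    assert a.characteristic_path_length == 1.0
    assert a.shortest_path_count == 20  # ordered pairs: 5*4


def test_star_centralization_and_heterogeneity():
    assert whole_network_attributes(nx.star_graph(5)).centralization == (
        pytest.approx(1.0)
    )
    a4 = whole_network_attributes(nx.star_graph(3))  # 4-node star
    # degrees (3,1,1,1): population variance 0.75, mean 1.5
    assert a4.heterogeneity == pytest.approx(np.sqrt(0.75) / 1.5)
    assert a4.heterogeneity == pytest.approx(0.5774, abs=1e-4)


def test_density_identity_and_pair_count_consistency():
    g = nx.gnm_random_graph(30, 60, seed=3)
    a = whole_network_attributes(g)
    assert a.density * (a.n_nodes - 1) == pytest.approx(a.average_neighbours)
    assert a.average_neighbours == pytest.approx(2 * a.n_edges / a.n_nodes)
    if nx.is_connected(g):
        assert a.shortest_path_count == a.n_nodes * (a.n_nodes - 1)


def test_disconnected_pair_count_excludes_unreachable():
    g = nx.Graph([(0, 1), (2, 3)])
    a = whole_network_attributes(g)
    assert a.shortest_path_count == 4  # two ordered pairs per component
    assert a.characteristic_path_length == 1.0


def test_empty_graph_error():
    with pytest.raises(MetricsError, match="empty"):
        whole_network_attributes(nx.Graph())


def test_isolated_pair_centralities():
    g = nx.Graph([("a", "b")])
    nodes = node_centralities(g)
    assert np.allclose(nodes["NCC"], 1.0)
    assert np.allclose(nodes["NBC"], 0.0)
    edges = edge_centralities(g)
    assert np.allclose(edges["EBC"], 2.0)


def test_star_hub_betweenness_is_one():
    nodes = node_centralities(nx.star_graph(6))
    assert nodes.loc[0, "NBC"] == pytest.approx(1.0)
    assert np.allclose(nodes.drop(index=0)["NBC"], 0.0)


def test_path_graph_closeness_and_betweenness():
    g = nx.path_graph(["a", "b", "c", "d"])
    nodes = node_centralities(g)
    assert nodes.loc["b", "NBC"] == pytest.approx(2.0 / 3.0)
    assert nodes.loc["b", "NCC"] == pytest.approx(0.75)


def test_triangle_edge_betweenness_is_two():
    edges = edge_centralities(nx.complete_graph(3))
    assert np.allclose(edges["EBC"], 2.0)


def test_bridge_between_two_triangles_matches_brute_force():
    g = nx.Graph(
        [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
    )
    _, edge_oracle = brute_force_betweenness(g)
    edges = edge_centralities(g)
    for _, row in edges.iterrows():
        key = tuple(sorted((row["species_a"], row["species_b"])))
        assert row["EBC"] == pytest.approx(edge_oracle[key])
    # the bridge carries all 9 ordered pairs each way: EBC = 18
    bridge = edges.query("species_a == 2 and species_b == 3")
    assert bridge["EBC"].iloc[0] == pytest.approx(18.0)


def test_brandes_equals_brute_force_on_random_graphs():
    rng = np.random.default_rng(0)
    for _ in range(30):
        n = int(rng.integers(4, 12))
        g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.7), seed=int(rng.integers(1e6)))
        if g.number_of_edges() == 0:
            continue
        node_oracle, edge_oracle = brute_force_betweenness(g)
        nodes = node_centralities(g)
        for v, b in node_oracle.items():
            assert nodes.loc[v, "NBC"] == pytest.approx(b, abs=1e-12)
        edges = edge_centralities(g)
        for _, row in edges.iterrows():
            key = tuple(sorted((row["species_a"], row["species_b"])))
            assert row["EBC"] == pytest.approx(edge_oracle[key], abs=1e-9)


def test_ebc_sum_equals_total_geodesic_length():
    rng = np.random.default_rng(1)
    for _ in range(10):
        g = nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(1e6)))
        if g.number_of_edges() == 0:
            continue
        a = whole_network_attributes(g)
        total_len = a.characteristic_path_length * a.shortest_path_count
        assert edge_centralities(g)["EBC"].sum() == pytest.approx(total_len)


def test_adding_edge_never_increases_path_length():
    # holds on connected graphs (new edges can only shorten geodesics)
    rng = np.random.default_rng(2)
    checked = 0
    seed = 0
    while checked < 10:
        seed += 1
        g = nx.gnp_random_graph(12, 0.3, seed=seed)
        if not nx.is_connected(g):
            continue
        base = whole_network_attributes(g).characteristic_path_length
        non_edges = list(nx.non_edges(g))
        u, v = non_edges[int(rng.integers(len(non_edges)))]
        g.add_edge(u, v)
        assert whole_network_attributes(g).characteristic_path_length <= base
        checked += 1
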