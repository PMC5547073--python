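"""Unit and property tests for the graph metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from entronet import (
    Network,
    clustering_coefficient,
    compute_metric_set,
    degree_distribution,
    degree_moments,
    global_efficiency,
    local_efficiency,
    mean_geodesic_distance,
    moments_of_degrees,
    network_from_edgelist_text,
    network_to_edgelist_text,
    shannon_entropy,
)

from conftest import random_network_factory


def cycle(n):
    return Network.from_edges(n, [(i, (i + 1) % n) for i in range(n)])


def complete(n):
    return Network.from_edges(n, [(i, j) for i in range(n) for j in range(i + 1, n)])


def path(n):
    return Network.from_edges(n, [(i, i + 1) for i in range(n - 1)])


def star(n):
    return Network.from_edges(n, [(0, i) for i in range(1, n)])


class TestNetworkInvariants:
    def test_rejects_self_loops_and_out_of_range(self):
        with pytest.raises(ValueError):
            Network.from_edges(3, [(1, 1)])
        with pytest.raises(ValueError):
            Network.from_edges(3, [(0, 5)])

    def test_duplicate_and_reversed_edges_collapse(self):
        net = Network.from_edges(3, [(0, 1), (1, 0), (0, 1)])
        assert net.n_edges == 1

    def test_adjacency_roundtrip_symmetric(self):
        net = Network.from_edges(4, [(0, 1), (2, 3), (1, 2)])
        a = net.adjacency_matrix()
        assert np.array_equal(a, a.T)
        assert Network.from_adjacency(a) == net


class TestDegreeDistribution:
    @pytest.mark.parametrize(
        "net,expected",
        [
            (cycle(4), {2: 1.0}),
            (path(3), {1: 2 / 3, 2: 1 / 3}),
            (Network.from_edges(5, []), {0: 1.0}),
        ],
    )
    def test_examples(self, net, expected):
        probs = degree_distribution(net).probabilities
        assert set(probs) == set(expected)
        for k, p in expected.items():
            assert probs[k] == pytest.approx(p, abs=1e-15)

    def test_regular_graph_entropy_zero(self):
        for net in (cycle(6), complete(5)):
            assert shannon_entropy(degree_distribution(net)) == 0.0

    def test_two_equiprobable_classes(self):
        # 4 nodes: two of degree 1, two of degree 2
        net = Network.from_edges(4, [(0, 1), (1, 2), (2, 3)])
        assert shannon_entropy(degree_distribution(net)) == pytest.approx(math.log(2))

    def test_hand_computed_mixed_distribution(self):
        # degrees [2,2,2,3,3,4] -> P = {1/2, 1/3, 1/6} -> S = 1.01140 nats
        net = Network.from_edges(
            6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0), (0, 3), (3, 5)]
        )
        assert sorted(net.degrees()) == [2, 2, 2, 3, 3, 4]
        s = shannon_entropy(degree_distribution(net))
        expected = -(0.5 * math.log(0.5) + (1 / 3) * math.log(1 / 3) + (1 / 6) * math.log(1 / 6))
        assert s == pytest.approx(expected, abs=1e-12)
        assert s == pytest.approx(1.0114, abs=5e-5)


class TestDegreeMoments:
    def test_two_two_four_four_by_hand(self):
        # m2 = mean((d-3)^2) = 1, m4 = 1, kurtosis = m4/m2^2 = 1
        var, kurt = moments_of_degrees([2, 2, 4, 4])
        assert var == pytest.approx(1.0, abs=1e-15)
        assert kurt == pytest.approx(1.0, abs=1e-15)

    def test_population_variance_one_to_six(self):
        # population m2 of [1..6] is 35/12 = 2.91666...
        var, _ = moments_of_degrees([1, 2, 3, 4, 5, 6])
        assert var == pytest.approx(35 / 12, abs=1e-12)
        assert var == pytest.approx(2.9167, abs=5e-5)

    def test_network_moments_match_multiset(self):
        net = Network.from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4), (1, 3)])
        assert degree_moments(net) == moments_of_degrees(net.degrees())

    def test_regular_graph_kurtosis_missing(self):
        var, kurt = degree_moments(cycle(5))
        assert var == 0.0
        assert kurt is None


class TestDistanceMetrics:
    @pytest.mark.parametrize(
        "net,expected_d",
        [
            (complete(5), 1.0),
            (path(3), 4 / 3),
            (Network.from_edges(4, [(0, 1), (2, 3)]), math.inf),
        ],
    )
    def test_mean_geodesic(self, net, expected_d):
        assert mean_geodesic_distance(net) == pytest.approx(expected_d)

    @pytest.mark.parametrize(
        "net,expected",
        [
            (complete(4), 1.0),
            (path(3), 5 / 6),
            (Network.from_edges(3, []), 0.0),
        ],
    )
    def test_global_efficiency(self, net, expected):
        assert global_efficiency(net) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "net,expected",
        [
            (complete(3), 1.0),
            (star(4), 0.0),
            (Network.from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]), 5 / 6),
        ],
    )
    def test_clustering(self, net, expected):
        assert clustering_coefficient(net) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "net,expected",
        [
            (complete(4), 1.0),
            (star(4), 0.0),
            (Network.from_edges(4, [(0, 1), (0, 2), (1, 2), (2, 3)]), 7 / 12),
        ],
    )
    def test_local_efficiency(self, net, expected):
        assert local_efficiency(net) == pytest.approx(expected, abs=1e-12)


class TestProperties:
    def test_entropy_bounded_by_log_distinct_degrees(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            net = random_network_factory(rng)
            dist = degree_distribution(net)
            s = shannon_entropy(dist)
            assert -1e-12 <= s <= math.log(len(dist.probabilities)) + 1e-12

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            net = random_network_factory(rng)
            perm = rng.permutation(net.n_nodes).tolist()
            s1 = shannon_entropy(degree_distribution(net))
            s2 = shannon_entropy(degree_distribution(net.relabeled(perm)))
            assert s1 == pytest.approx(s2, abs=1e-12)

    def test_efficiency_vs_inverse_distance(self):
        # connected graphs: E_g >= 1/D (harmonic-arithmetic mean inequality)
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 30:
            net = random_network_factory(rng)
            d = mean_geodesic_distance(net)
            if math.isinf(d):
                continue
            assert global_efficiency(net) >= 1.0 / d - 1e-12
            checked += 1

    def test_edge_addition_monotonicity(self):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 30:
            net = random_network_factory(rng)
            if math.isinf(mean_geodesic_distance(net)):
                continue
            missing = [
                (i, j)
                for i in range(net.n_nodes)
                for j in range(i + 1, net.n_nodes)
                if (i, j) not in net.edges
            ]
            if not missing:
                continue
            extra = missing[int(rng.integers(len(missing)))]
            bigger = Network.from_edges(net.n_nodes, list(net.edges) + [extra])
            assert mean_geodesic_distance(bigger) <= mean_geodesic_distance(net) + 1e-12
            assert global_efficiency(bigger) >= global_efficiency(net) - 1e-12
            checked += 1

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_metric_set_consistent_with_parts(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network_factory(rng, n_max=10)
        ms = compute_metric_set(net)
        assert ms.entropy_nats == pytest.approx(
            shannon_entropy(degree_distribution(net)), abs=1e-12
        )
        assert ms.clustering == pytest.approx(clustering_coefficient(net), abs=1e-12)
        assert ms.global_efficiency == pytest.approx(global_efficiency(net), abs=1e-12)
        if math.isinf(ms.mean_geodesic):
            assert math.isinf(mean_geodesic_distance(net))
        else:
            assert ms.mean_geodesic == pytest.approx(mean_geodesic_distance(net), abs=1e-12)


class TestSerialization:
    def test_edgelist_roundtrip(self):
        net = Network.from_edges(6, [(0, 1), (2, 5), (3, 4), (1, 2)])
        assert network_from_edgelist_text(network_to_edgelist_text(net)) == net

    def test_graphml_written(self, tmp_path):
        import networkx as nx

        net = Network.from_edges(4, [(0, 1), (1, 2), (2, 3)])
        path = tmp_path / "net.graphml"
        from entronet import network_to_graphml

        network_to_graphml(net, str(path))
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 3
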