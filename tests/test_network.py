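"""Tripartite network construction and the three topology metrics."""

import numpy as np
import pytest

from phytonet import core_io
from phytonet.errors import DegenerateNetworkError
from phytonet.models import GeneSetAnnotation
from phytonet.network import (
    TripartiteNetwork,
    betweenness,
    build_network,
    closeness,
    degree,
)

from conftest import random_tripartite
from oracles import betweenness_exact, closeness_exact


def path_net(*chain):
    """A path graph alternating component/target/pathway partitions."""
    cycle = ["component", "target", "pathway", "target"]
    nodes = [(node, cycle[i % 4]) for i, node in enumerate(chain)]
    return TripartiteNetwork.from_edges(nodes, list(zip(chain, chain[1:])))


class TestBuildNetwork:
    def test_minimal_chain_has_three_nodes_two_edges(self):
        t = GeneSetAnnotation("P1", "p", frozenset({"G"}), "kegg")
        net = build_network({"c": {"G"}}, [t], {"G"})
        assert net.summary() == {
            "n_nodes": 3, "n_edges": 2,
            "n_components": 1, "n_targets": 1, "n_pathways": 1,
        }

    def test_edge_count_matches_direct_counting(self):
        rng = np.random.default_rng(13)
        genes = [f"G{i}" for i in range(30)]
        per_compound = {
            f"c{j}": set(rng.choice(genes, size=rng.integers(1, 8), replace=False))
            for j in range(10)
        }
        effective = set(genes[:20])
        terms = [
            GeneSetAnnotation(f"P{j}", "p",
                              frozenset(rng.choice(genes, size=6, replace=False)),
                              "kegg")
            for j in range(4)
        ]
        net = build_network(per_compound, terms, effective)
        expected_ct = sum(len(s & effective) for s in per_compound.values())
        expected_tp = sum(len(t.genes & effective) for t in terms)
        assert net.graph.number_of_edges() == expected_ct + expected_tp

    def test_empty_result_is_degenerate(self):
        with pytest.raises(DegenerateNetworkError):
            build_network({"c": {"G"}}, [], set())

    def test_same_partition_edges_are_rejected(self):
        with pytest.raises(ValueError, match="partitions"):
            TripartiteNetwork.from_edges(
                [("c1", "component"), ("c2", "component")], [("c1", "c2")]
            )

    def test_self_loops_are_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            TripartiteNetwork.from_edges([("c1", "component")], [("c1", "c1")])


class TestDegree:
    def test_star_center_degree_equals_leaf_count(self):
        leaves = [f"t{i}" for i in range(7)]
        net = TripartiteNetwork.from_edges(
            [("hub", "component")] + [(t, "target") for t in leaves],
            [("hub", t) for t in leaves],
        )
        assert degree(net)["hub"] == 7

    def test_handshake_lemma(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            net = random_tripartite(rng)
            assert sum(degree(net).values()) == 2 * net.graph.number_of_edges()

    def test_reference_network_component_degrees(self):
        net = core_io.reference_component_network()
        deg = degree(net)
        assert deg["HSYA (-11, +17)"] == 2
        assert deg["Quercetin (+40)"] == 12


class TestCloseness:
    def test_three_node_path(self):
        net = path_net("a", "b", "c")
        clo = closeness(net)
        assert clo["b"] == pytest.approx(1.0)
        assert clo["a"] == pytest.approx(2 / 3)

    def test_complete_bipartite_pair(self):
        # two nodes joined by an edge: both at distance 1 from everything
        net = path_net("a", "b")
        assert all(v == pytest.approx(1.0) for v in closeness(net).values())

    def test_matches_floyd_warshall_oracle_on_random_graphs(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            net = random_tripartite(rng, max_nodes=12)
            nodes = sorted(net.graph.nodes)
            edges = {tuple(sorted(e)) for e in net.graph.edges}
            expected = closeness_exact(nodes, edges)
            got = closeness(net)
            for v in nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-12)


class TestBetweenness:
    def test_three_node_path(self):
        bet = betweenness(path_net("a", "b", "c"))
        assert bet["b"] == pytest.approx(1.0)
        assert bet["a"] == bet["c"] == 0.0

    def test_tiny_networks_are_all_zero(self):
        assert set(betweenness(path_net("a", "b")).values()) == {0.0}

    def test_matches_path_enumeration_oracle_on_random_graphs(self):
        rng = np.random.default_rng(37)
        for _ in range(200):
            net = random_tripartite(rng, max_nodes=10)
            nodes = sorted(net.graph.nodes)
            edges = {tuple(sorted(e)) for e in net.graph.edges}
            expected = betweenness_exact(nodes, edges)
            got = betweenness(net)
            for v in nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-12)


class TestInvariances:
    @pytest.mark.parametrize("seed", range(10))
    def test_metrics_invariant_under_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        net = random_tripartite(rng)
        mapping = {v: f"x_{v}" for v in net.graph.nodes}
        relabeled = TripartiteNetwork.from_edges(
            [(mapping[v], net.partition_of(v)) for v in net.graph.nodes],
            [(mapping[u], mapping[v]) for u, v in net.graph.edges],
        )
        for metric in (degree, closeness, betweenness):
            original = metric(net)
            renamed = metric(relabeled)
            for v, value in original.items():
                assert renamed[mapping[v]] == pytest.approx(value)

    def test_no_edge_joins_nodes_of_one_partition(self):
        rng = np.random.default_rng(41)
        for _ in range(30):
            net = random_tripartite(rng)
            for u, v in net.graph.edges:
                assert net.partition_of(u) != net.partition_of(v)
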