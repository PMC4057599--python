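"""Integrated-network assembly and gatewayness scoring."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import clique_edges, make_cluster, make_state_network
from gatewaynet.gateway import (
    DegeneratePairError,
    build_integrated,
    find_gateway_sets,
    gateway_records,
    gatewayness,
    gateways_at_thresholds,
    max_gatewayness_per_node,
)
from gatewaynet.synthdata import PlantedDesign, generate_two_state
from gatewaynet.corrnet import build_state_network


def _two_clique_instance(shared=("s",), x_extra=4, y_extra=4):
    """Two cliques, one per state, overlapping exactly in ``shared``."""
    x_nodes = [f"x{i}" for i in range(x_extra)] + list(shared)
    y_nodes = [f"y{i}" for i in range(y_extra)] + list(shared)
    net1 = make_state_network("YNG", clique_edges(x_nodes), nodes=y_nodes)
    net2 = make_state_network("MID", clique_edges(y_nodes), nodes=x_nodes)
    cx = make_cluster("YNG:1", "YNG", x_nodes, net1)
    cy = make_cluster("MID:1", "MID", y_nodes, net2)
    return net1, net2, cx, cy


class TestBuildIntegrated:
    def test_disjoint_clusters_give_disjoint_union(self):
        net1 = make_state_network("YNG", clique_edges("abcde"))
        net2 = make_state_network("MID", clique_edges("fghij"))
        cx = make_cluster("YNG:1", "YNG", "abcde", net1)
        cy = make_cluster("MID:1", "MID", "fghij", net2)
        integrated = build_integrated([cx, cy], net1, net2)
        assert set(integrated.graph.nodes) == set("abcdefghij")
        assert integrated.graph.number_of_edges() == 20
        assert not nx.has_path(integrated.graph, "a", "f")

    def test_identical_edge_in_both_states_labeled_both(self):
        net1 = make_state_network("YNG", clique_edges("abcde"))
        net2 = make_state_network("MID", [("a", "b")], nodes="abcde")
        cx = make_cluster("YNG:1", "YNG", "abcde", net1)
        integrated = build_integrated([cx], net1, net2)
        assert integrated.graph["a"]["b"]["states"] == {"YNG", "MID"}
        assert integrated.graph["a"]["c"]["states"] == {"YNG"}

    def test_edge_labels_match_per_state_membership_lookup(self):
        rng = np.random.default_rng(31)
        nodes = [f"n{i}" for i in range(12)]
        g1 = nx.gnp_random_graph(12, 0.5, seed=1)
        g2 = nx.gnp_random_graph(12, 0.5, seed=2)
        net1 = make_state_network("YNG", [(nodes[u], nodes[v]) for u, v in g1.edges()], nodes)
        net2 = make_state_network("MID", [(nodes[u], nodes[v]) for u, v in g2.edges()], nodes)
        clusters = [
            make_cluster("YNG:1", "YNG", nodes[:6], net1),
            make_cluster("YNG:2", "YNG", nodes[4:9], net1),
            make_cluster("MID:1", "MID", nodes[5:], net2),
        ]
        integrated = build_integrated(clusters, net1, net2)
        node_set = set().union(*(c.member_nodes for c in clusters))
        for u, v, data in integrated.graph.edges(data=True):
            expected = set()
            if net1.graph.has_edge(u, v):
                expected.add("YNG")
            if net2.graph.has_edge(u, v):
                expected.add("MID")
            assert data["states"] == expected
        # completeness: every in-scope state edge appears
        for net in (net1, net2):
            for u, v in net.graph.edges():
                if u in node_set and v in node_set:
                    assert integrated.graph.has_edge(u, v)

    def test_unknown_cluster_nodes_rejected(self):
        net1 = make_state_network("YNG", clique_edges("abcde"))
        net2 = make_state_network("MID", [], nodes="abcde")
        ghost = make_cluster("YNG:1", "YNG", "abcde", net1)
        object.__setattr__(ghost, "member_nodes", frozenset("abcdez"))
        with pytest.raises(ValueError):
            build_integrated([ghost], net1, net2)


class TestFindGatewaySets:
    def test_single_shared_node(self):
        net1, net2, cx, cy = _two_clique_instance()
        integrated = build_integrated([cx, cy], net1, net2)
        [(pair, shared)] = find_gateway_sets(integrated)
        assert shared == {"s"}

    def test_half_size_restriction_excludes_large_overlap(self):
        # |X| = |Y| = 4 with |S| = 3 must be excluded
        net1 = make_state_network("YNG", clique_edges(["s1", "s2", "s3", "x0"]))
        net2 = make_state_network("MID", clique_edges(["s1", "s2", "s3", "y0"]),
                                  nodes=["x0"])
        net1.graph.add_node("y0")
        cx = make_cluster("YNG:1", "YNG", ["s1", "s2", "s3", "x0"], net1)
        cy = make_cluster("MID:1", "MID", ["s1", "s2", "s3", "y0"], net2)
        integrated = build_integrated([cx, cy], net1, net2)
        assert find_gateway_sets(integrated) == []

    def test_identical_clusters_excluded_as_trivial(self):
        nodes = list("abcde")
        net1 = make_state_network("YNG", clique_edges(nodes))
        net2 = make_state_network("MID", clique_edges(nodes))
        cx = make_cluster("YNG:1", "YNG", nodes, net1)
        cy = make_cluster("MID:1", "MID", nodes, net2)
        integrated = build_integrated([cx, cy], net1, net2)
        assert find_gateway_sets(integrated) == []

    def test_exact_half_overlap_allowed(self):
        # |S| = 2 with clusters of size >= 4 on either side: 2*|S| <= min size
        shared = ["s1", "s2"]
        net1, net2, cx, cy = _two_clique_instance(shared=shared, x_extra=4, y_extra=4)
        integrated = build_integrated([cx, cy], net1, net2)
        [(pair, found)] = find_gateway_sets(integrated)
        assert found == set(shared)


class TestGatewayness:
    def test_sole_gateway_scores_exactly_one(self):
        net1, net2, cx, cy = _two_clique_instance()
        integrated = build_integrated([cx, cy], net1, net2)
        assert gatewayness("s", (cx, cy), integrated) == 1.0

    def test_symmetric_pair_splits_evenly(self):
        net1, net2, cx, cy = _two_clique_instance(shared=["s1", "s2"])
        integrated = build_integrated([cx, cy], net1, net2)
        assert gatewayness("s1", (cx, cy), integrated) == pytest.approx(0.5)
        assert gatewayness("s2", (cx, cy), integrated) == pytest.approx(0.5)

    def test_fourteen_node_instance_matches_exhaustive_edge_count(self):
        # X = {x0..x5, s1, s2}, Y = {y0..y3, s1, s2, s3}: asymmetric clusters,
        # S = {s1, s2} (s3 lives only in Y), uneven cross-edge counts.
        x_members = [f"x{i}" for i in range(6)] + ["s1", "s2"]
        y_members = [f"y{i}" for i in range(4)] + ["s1", "s2", "s3"]
        e1 = clique_edges(x_members)
        e2 = clique_edges(y_members)
        all_nodes = sorted(set(x_members) | set(y_members))
        net1 = make_state_network("YNG", e1, nodes=all_nodes)
        net2 = make_state_network("MID", e2, nodes=all_nodes)
        cx = make_cluster("YNG:1", "YNG", x_members, net1)
        cy = make_cluster("MID:1", "MID", y_members, net2)
        integrated = build_integrated([cx, cy], net1, net2)
        shared = set(x_members) & set(y_members)
        assert shared == {"s1", "s2"}
        # oracle: enumerate every integrated edge and classify by hand
        pair_nodes = set(x_members) | set(y_members)
        counts = {}
        for s in shared:
            counts[s] = sum(
                1
                for u, v in integrated.graph.edges()
                if s in (u, v)
                and {u, v} - {s} <= pair_nodes - shared
            )
        total = sum(counts.values())
        for s in shared:
            assert gatewayness(s, (cx, cy), integrated) == pytest.approx(
                counts[s] / total
            )
        assert total > 0

    def test_degenerate_pair_with_no_cross_edges_raises(self):
        # clusters overlap in s, but s has no edge to any non-gateway node
        net1 = make_state_network("YNG", clique_edges("abcd"), nodes=["s"])
        net2 = make_state_network("MID", clique_edges("wxyz"), nodes=["s"])
        cx = make_cluster("YNG:1", "YNG", ["a", "b", "c", "d", "s"], net1)
        cy = make_cluster("MID:1", "MID", ["w", "x", "y", "z", "s"], net2)
        integrated = build_integrated([cx, cy], net1, net2)
        with pytest.raises(DegeneratePairError):
            gatewayness("s", (cx, cy), integrated)


class TestGatewayProperties:
    def _random_instance(self, seed):
        rng = np.random.default_rng(seed)
        n_shared = rng.integers(1, 4)
        shared = [f"s{i}" for i in range(n_shared)]
        x_extra = int(rng.integers(2 * n_shared, 2 * n_shared + 5))
        y_extra = int(rng.integers(2 * n_shared, 2 * n_shared + 5))
        return _two_clique_instance(shared, x_extra, y_extra)

    @pytest.mark.parametrize("seed", range(12))
    def test_gatewayness_sums_to_one_per_gateway_set(self, seed):
        net1, net2, cx, cy = self._random_instance(seed)
        integrated = build_integrated([cx, cy], net1, net2)
        records = gateway_records(integrated)
        assert records
        assert sum(r.gatewayness for r in records) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_gateway_set_is_a_cut_between_the_clusters(self, seed):
        net1, net2, cx, cy = self._random_instance(seed)
        integrated = build_integrated([cx, cy], net1, net2)
        [(_, shared)] = find_gateway_sets(integrated)
        sub = integrated.graph.subgraph(
            (cx.member_nodes | cy.member_nodes) - shared
        )
        x_only = cx.member_nodes - shared
        y_only = cy.member_nodes - shared
        for a, b in itertools.product(x_only, y_only):
            assert not nx.has_path(sub, a, b)

    def test_invariant_under_node_relabeling(self):
        net1, net2, cx, cy = _two_clique_instance(shared=["s1", "s2"], x_extra=5)
        integrated = build_integrated([cx, cy], net1, net2)
        base = {r.node: r.gatewayness for r in gateway_records(integrated)}

        mapping = {n: f"Z{idx}" for idx, n in enumerate(sorted(integrated.graph.nodes))}
        relabel = lambda members: frozenset(mapping[m] for m in members)
        net1b = make_state_network(
            "YNG", [(mapping[u], mapping[v]) for u, v in net1.graph.edges()],
            nodes=[mapping[n] for n in net1.graph.nodes],
        )
        net2b = make_state_network(
            "MID", [(mapping[u], mapping[v]) for u, v in net2.graph.edges()],
            nodes=[mapping[n] for n in net2.graph.nodes],
        )
        cxb = make_cluster("YNG:1", "YNG", relabel(cx.member_nodes), net1b)
        cyb = make_cluster("MID:1", "MID", relabel(cy.member_nodes), net2b)
        permuted = build_integrated([cxb, cyb], net1b, net2b)
        renamed = {r.node: r.gatewayness for r in gateway_records(permuted)}
        assert renamed == {mapping[n]: v for n, v in base.items()}


class TestGatewaysAtThresholds:
    def test_planted_gateway_found_at_every_surviving_threshold(self):
        design = PlantedDesign(seed=21)
        m1, m2 = generate_two_state(design)
        net1 = build_state_network(m1)
        net2 = build_state_network(m2)
        table = gateways_at_thresholds(net1, net2, [0.65, 0.75, 0.85])
        assert list(table["node"]) == ["GW1"]
        row = table.iloc[0]
        for col in ("gatewayness_65", "gatewayness_75", "gatewayness_85"):
            assert row[col] == pytest.approx(1.0)

    def test_threshold_column_blank_when_cluster_dies(self):
        # The YNG cluster is K7 minus a 7-cycle: 4-regular, density 14/21 =
        # 0.667, so its gateway appears in the 65% column but not the 75% one.
        x_nodes = [f"x{i}" for i in range(6)] + ["s"]
        ring = list(zip(x_nodes, x_nodes[1:] + x_nodes[:1]))
        missing = {frozenset(e) for e in ring}
        e1 = [e for e in clique_edges(x_nodes) if frozenset(e) not in missing]
        y_nodes = [f"y{i}" for i in range(5)] + ["s"]
        net1 = make_state_network("YNG", e1, nodes=y_nodes)
        net2 = make_state_network("MID", clique_edges(y_nodes), nodes=x_nodes)
        table = gateways_at_thresholds(net1, net2, [0.65, 0.75])
        assert len(table) == 1
        row = table.iloc[0]
        assert row["node"] == "s"
        assert row["gatewayness_65"] == pytest.approx(1.0)
        assert np.isnan(row["gatewayness_75"])

    def test_empty_intersection_gives_empty_table(self):
        net1 = make_state_network("YNG", clique_edges("abcde"), nodes="fghij")
        net2 = make_state_network("MID", clique_edges("fghij"), nodes="abcde")
        table = gateways_at_thresholds(net1, net2, [0.65])
        assert table.empty


def test_max_gatewayness_summary_picks_largest_per_node():
    from gatewaynet.gateway import GatewayRecord

    records = [
        GatewayRecord("g1", ("X1", "Y1"), 3, 0.4),
        GatewayRecord("g1", ("X2", "Y1"), 5, 0.9),
        GatewayRecord("g2", ("X1", "Y1"), 2, 0.6),
    ]
    assert max_gatewayness_per_node(records) == {"g1": 0.9, "g2": 0.6}
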