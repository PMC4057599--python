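"""Gateway-node identification on the integrated two-state network.

Dense clusters from two state-specific correlation networks are merged into
one integrated graph whose edges remember which state(s) they came from. For
every cross-state cluster pair (X, Y) the gateway set is the node overlap
S = V(X) ∩ V(Y); each member's *gatewayness* is the fraction of the
cluster-bridging edges that pass through it,

    gatewayness(s) = e(s) / Σ_{s'∈S} e(s'),

where e(s) counts integrated-graph edges joining s to (V(X) ∪ V(Y)) \\ S —
edges between two gateway nodes do not bridge cluster to gateway and are
excluded. Scores over one gateway set always sum to 1, and a sole gateway
scores exactly 1.00. Removing S disconnects the X-only nodes from the Y-only
nodes in the induced subgraph: the gateway set is a node cut set between the
two clusters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .corrnet import StateNetwork
from .denseclust import DenseCluster, filter_by_density, mcode_clusters

logger = logging.getLogger(__name__)


class DegeneratePairError(ValueError):
    """All per-gateway cross-edge counts are zero for a cluster pair."""


@dataclass
class IntegratedNetwork:
    """Union graph over the retained clusters of both states.

    Each edge carries ``states``: the set of state labels whose network
    contains it (both labels for dual-state edges).
    """

    graph: nx.Graph
    source_clusters: list[DenseCluster]
    state_labels: tuple[str, str]

    def clusters_of_state(self, label: str) -> list[DenseCluster]:
        return [c for c in self.source_clusters if c.state_label == label]


@dataclass
class GatewayRecord:
    """One gateway node for one qualifying cluster pair."""

    node: str
    cluster_pair: tuple[str, str]
    cross_edge_count: int
    gatewayness: float
    density_threshold: float | None = None


def build_integrated(
    clusters: list[DenseCluster],
    net1: StateNetwork,
    net2: StateNetwork,
) -> IntegratedNetwork:
    """Form the integrated graph over the union of cluster member nodes.

    The edge set is every net1/net2 edge with both endpoints inside the node
    union, labeled by originating state; an edge present in both networks is
    stored once with both labels.
    """
    labels = {c.state_label for c in clusters}
    if not labels <= {net1.state_label, net2.state_label}:
        raise ValueError(
            f"clusters reference states {labels} but networks are "
            f"{net1.state_label!r} and {net2.state_label!r}"
        )
    node_set: set[str] = set()
    for c in clusters:
        unknown = set(c.member_nodes) - (net1.nodes | net2.nodes)
        if unknown:
            raise ValueError(
                f"cluster {c.cluster_id} references unknown nodes: {sorted(unknown)[:5]}"
            )
        node_set |= c.member_nodes

    graph = nx.Graph()
    graph.add_nodes_from(node_set)
    for net in (net1, net2):
        for u, v, data in net.graph.edges(data=True):
            if u in node_set and v in node_set:
                if graph.has_edge(u, v):
                    graph[u][v]["states"] = graph[u][v]["states"] | {net.state_label}
                else:
                    graph.add_edge(
                        u, v, states=frozenset({net.state_label}), **{
                            k: data[k] for k in ("rho", "p_value") if k in data
                        }
                    )
    return IntegratedNetwork(
        graph=graph,
        source_clusters=list(clusters),
        state_labels=(net1.state_label, net2.state_label),
    )


def find_gateway_sets(
    integrated: IntegratedNetwork,
    enforce_size_restriction: bool = True,
) -> list[tuple[tuple[DenseCluster, DenseCluster], frozenset[str]]]:
    """Gateway sets S = V(X) ∩ V(Y) over all cross-state cluster pairs.

    A pair is reported only when S is nonempty and (unless the restriction is
    suspended, as in null-model analysis) |S| <= min(|V(X)|, |V(Y)|) / 2.
    The size rule guarantees the clusters are genuinely different and rules
    out the trivial case V(X) = V(Y) = S. Pairs are ordered by cluster ids.
    """
    s1, s2 = integrated.state_labels
    xs = sorted(integrated.clusters_of_state(s1), key=lambda c: c.cluster_id)
    ys = sorted(integrated.clusters_of_state(s2), key=lambda c: c.cluster_id)
    out = []
    for x, y in itertools.product(xs, ys):
        shared = x.member_nodes & y.member_nodes
        if not shared:
            continue
        if enforce_size_restriction and 2 * len(shared) > min(x.size, y.size):
            logger.info(
                "pair (%s, %s): |S|=%d exceeds half the smaller cluster, excluded",
                x.cluster_id, y.cluster_id, len(shared),
            )
            continue
        out.append(((x, y), frozenset(shared)))
    return out


def cross_edge_count(
    s: str,
    cluster_pair: tuple[DenseCluster, DenseCluster],
    integrated: IntegratedNetwork,
    gateway_set: frozenset[str] | None = None,
) -> int:
    """e(s): integrated-graph edges from s into (V(X) ∪ V(Y)) \\ S.

    When S covers the entire pair-node union (the whole-network null-model
    degenerate case) there are no non-gateway neighbors by construction; the
    count then falls back to all integrated edges incident to s, which is the
    only reading under which every node of two cluster-identical networks can
    be scored.
    """
    x, y = cluster_pair
    if gateway_set is None:
        gateway_set = frozenset(x.member_nodes & y.member_nodes)
    pair_nodes = x.member_nodes | y.member_nodes
    targets = pair_nodes - gateway_set
    if not targets:
        return sum(1 for nb in integrated.graph.neighbors(s) if nb in pair_nodes)
    return sum(1 for nb in integrated.graph.neighbors(s) if nb in targets)


def gatewayness(
    s: str,
    cluster_pair: tuple[DenseCluster, DenseCluster],
    integrated: IntegratedNetwork,
) -> float:
    """Fraction of the pair's bridging edges passing through gateway ``s``."""
    x, y = cluster_pair
    gateway_set = frozenset(x.member_nodes & y.member_nodes)
    if s not in gateway_set:
        raise ValueError(f"{s!r} is not in the gateway set of this pair")
    total = sum(
        cross_edge_count(t, cluster_pair, integrated, gateway_set)
        for t in gateway_set
    )
    if total == 0:
        raise DegeneratePairError(
            f"no cross edges through any gateway of pair "
            f"({x.cluster_id}, {y.cluster_id})"
        )
    return cross_edge_count(s, cluster_pair, integrated, gateway_set) / total


def gateway_records(
    integrated: IntegratedNetwork,
    density_threshold: float | None = None,
    enforce_size_restriction: bool = True,
) -> list[GatewayRecord]:
    """Score every gateway of every qualifying cluster pair."""
    records: list[GatewayRecord] = []
    for (x, y), shared in find_gateway_sets(integrated, enforce_size_restriction):
        counts = {
            s: cross_edge_count(s, (x, y), integrated, shared) for s in shared
        }
        total = sum(counts.values())
        if total == 0:
            logger.warning(
                "pair (%s, %s) has no cross edges, dropped", x.cluster_id, y.cluster_id
            )
            continue
        for s in sorted(shared):
            records.append(
                GatewayRecord(
                    node=s,
                    cluster_pair=(x.cluster_id, y.cluster_id),
                    cross_edge_count=counts[s],
                    gatewayness=counts[s] / total,
                    density_threshold=density_threshold,
                )
            )
    return records


def gateways_at_thresholds(
    net1: StateNetwork,
    net2: StateNetwork,
    thresholds: list[float] = (0.65, 0.75, 0.85),
    degree_cutoff: int = 4,
    k_core: int = 4,
) -> pd.DataFrame:
    """Full pipeline per density threshold: cluster, filter, integrate, score.

    Returns a wide table with one row per (node, cluster pair) and one
    gatewayness column per threshold — the shape used to present per-node
    gatewayness across 65/75/85% cluster densities. A blank cell means the
    node is not a gateway at that threshold.
    """
    if not thresholds:
        raise ValueError("need at least one density threshold")
    clusters1 = mcode_clusters(net1, degree_cutoff=degree_cutoff, k_core=k_core)
    clusters2 = mcode_clusters(net2, degree_cutoff=degree_cutoff, k_core=k_core)
    rows: dict[tuple[str, str, str], dict] = {}
    for thr in sorted(thresholds):
        retained = filter_by_density(clusters1, thr) + filter_by_density(clusters2, thr)
        if not retained:
            continue
        integrated = build_integrated(retained, net1, net2)
        for rec in gateway_records(integrated, density_threshold=thr):
            key = (rec.node, *rec.cluster_pair)
            row = rows.setdefault(
                key,
                {"node": rec.node, "cluster_x": rec.cluster_pair[0],
                 "cluster_y": rec.cluster_pair[1]},
            )
            row[f"gatewayness_{int(round(thr * 100))}"] = rec.gatewayness
    cols = ["node", "cluster_x", "cluster_y"] + [
        f"gatewayness_{int(round(t * 100))}" for t in sorted(thresholds)
    ]
    if not rows:
        return pd.DataFrame(columns=cols)
    table = pd.DataFrame(rows.values()).reindex(columns=cols)
    return table.sort_values(["node", "cluster_x", "cluster_y"]).reset_index(drop=True)


def max_gatewayness_per_node(records: list[GatewayRecord]) -> dict[str, float]:
    """Per-node summary when a node bridges several cluster pairs."""
    out: dict[str, float] = {}
    for rec in records:
        out[rec.node] = max(out.get(rec.node, 0.0), rec.gatewayness)
    return out
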