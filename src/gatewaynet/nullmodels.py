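"""Null-model network simulation and gateway significance testing.

Two null families are provided, matched in size to real co-expression
networks: Erdős–Rényi G(n, p) graphs (default n = 12300, p = 10/10000) and
static power-law scale-free graphs with degree exponent 2.5. Pairs of
independent draws over a shared node set stand in for the two biological
states; gateway analysis on such pairs — with density requirements not
enforced — yields the null gatewayness distribution against which observed
gateway scores are compared with a pooled-variance two-sample t-test.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
from scipy import stats

from .corrnet import StateNetwork
from .denseclust import DenseCluster, mcode_clusters
from .gateway import build_integrated, gateway_records

logger = logging.getLogger(__name__)


@dataclass
class NullEnsemble:
    """A reproducible collection of simulated network pairs."""

    model: str  # "er" | "scalefree"
    n_nodes: int
    parameter: float  # edge probability (ER) or degree exponent (scale-free)
    seed: int
    replicate_networks: list[tuple[StateNetwork, StateNetwork]]


def _node_ids(n: int) -> list[str]:
    width = len(str(n - 1)) if n else 1
    return [f"n{idx:0{width}d}" for idx in range(n)]


def _from_edgelist(n: int, edges, state_label: str) -> StateNetwork:
    ids = _node_ids(n)
    net = StateNetwork(state_label=state_label)
    net.graph.add_nodes_from(ids)
    net.graph.add_edges_from((ids[u], ids[v]) for u, v in edges)
    return net


def simulate_er_pair(
    n: int = 12300,
    p: float = 10 / 10000,
    seed: int = 0,
) -> tuple[StateNetwork, StateNetwork]:
    """Two independent G(n, p) draws over the same node set."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("edge probability must be in [0, 1]")
    pair = []
    for offset, label in enumerate(("NULL1", "NULL2")):
        g = nx.fast_gnp_random_graph(n, p, seed=seed + offset)
        pair.append(_from_edgelist(n, g.edges(), label))
    return tuple(pair)


def simulate_scalefree_pair(
    n: int,
    exponent: float = 2.5,
    m_edges: int | None = None,
    seed: int = 0,
) -> tuple[StateNetwork, StateNetwork]:
    """Two static power-law graphs with the requested degree exponent.

    ``m_edges`` matches each draw to a target real network's edge count.
    Self-loops and multi-edges are forbidden.
    """
    if exponent <= 2:
        raise ValueError("degree exponent must exceed 2")
    max_edges = n * (n - 1) // 2
    if m_edges is None:
        m_edges = min(6 * n, max_edges)
    if m_edges > max_edges:
        raise ValueError(f"m_edges={m_edges} exceeds the K_n bound {max_edges}")
    pair = []
    for offset, label in enumerate(("NULL1", "NULL2")):
        if m_edges == 0:
            pair.append(_from_edgelist(n, [], label))
            continue
        rng_seed = (seed + offset) % (2**31 - 1)
        ig.set_random_number_generator(random.Random(rng_seed))
        g = ig.Graph.Static_Power_Law(
            n, m_edges, exponent_out=exponent, exponent_in=-1,
            loops=False, multiple=False,
        )
        pair.append(_from_edgelist(n, g.get_edgelist(), label))
    return tuple(pair)


def _whole_network_cluster(net: StateNetwork) -> DenseCluster:
    nodes = frozenset(net.graph.nodes)
    k = len(nodes)
    e = net.graph.number_of_edges()
    density = 2.0 * e / (k * (k - 1)) if k > 1 else 0.0
    return DenseCluster(
        cluster_id=f"{net.state_label}:whole",
        state_label=net.state_label,
        member_nodes=nodes,
        density=density,
    )


def null_gateway_distribution(
    net1: StateNetwork,
    net2: StateNetwork,
    enforce_density: bool = False,
) -> list[float]:
    """Gatewayness values of every gateway found in a null network pair.

    With density unenforced — the null-model convention — a network in which
    dense-cluster detection finds nothing is treated as one whole-network
    cluster, and the gateway-set size restriction is suspended; two draws
    over a shared node set then make every shared node a gateway.
    """
    clusters1 = mcode_clusters(net1)
    clusters2 = mcode_clusters(net2)
    suspend_restriction = False
    if not enforce_density:
        if not clusters1:
            clusters1 = [_whole_network_cluster(net1)]
            suspend_restriction = True
        if not clusters2:
            clusters2 = [_whole_network_cluster(net2)]
            suspend_restriction = True
    if not clusters1 or not clusters2:
        return []
    integrated = build_integrated(clusters1 + clusters2, net1, net2)
    records = gateway_records(
        integrated, enforce_size_restriction=not suspend_restriction
    )
    return [r.gatewayness for r in records]


def count_null_gateways(
    net1: StateNetwork, net2: StateNetwork, enforce_density: bool = False
) -> int:
    """Number of distinct gateway nodes in a null pair."""
    clusters1 = mcode_clusters(net1) or [_whole_network_cluster(net1)]
    clusters2 = mcode_clusters(net2) or [_whole_network_cluster(net2)]
    integrated = build_integrated(clusters1 + clusters2, net1, net2)
    records = gateway_records(integrated, enforce_size_restriction=False)
    return len({r.node for r in records})


def gateway_significance(
    observed: list[float] | np.ndarray,
    null: list[float] | np.ndarray,
) -> float:
    """Two-sided pooled-variance Student t-test p-value, observed vs null."""
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.size < 2 or null.size < 1:
        raise ValueError("need >= 2 observed and >= 1 null gatewayness values")
    if observed.std() == 0 and null.std() == 0 and observed.mean() == null.mean():
        return 1.0
    result = stats.ttest_ind(observed, null, equal_var=True)
    return float(result.pvalue)


def significance_stars(p: float) -> str:
    """Star notation used in gateway summary tables."""
    if p < 0.0005:
        return "***"
    if p < 0.05:
        return "*"
    return ""
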