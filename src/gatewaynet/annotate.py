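"""Functional layers over gateway results.

Four operations: log2-odds lethality enrichment with a hypergeometric
p-value, per-term hypergeometric enrichment (deliberately uncorrected, with
an up/down direction flag), deepest-common-parent (DCP) edge annotation on an
ontology DAG, and ranking of gateways by the mean DCP score of their incident
edges.

DCP scoring: for an edge (g1, g2) with term sets T1 and T2, every common
ancestor a of some t1 ∈ T1 and t2 ∈ T2 is a candidate. Its depth is the
longest is_a path from a root down to a; its breadth is the sum of the
minimum upward hop counts from T1 to a and from T2 to a. The DCP is the
candidate maximizing score = depth − breadth (ties: deeper term, then
lexicographically smaller id). Genes annotated directly to a shared term get
breadth 0 and score equal to that term's depth; genes sharing only a root
score at most 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy import stats

from .gateway import GatewayRecord, IntegratedNetwork
from .io_formats import OntologyDAG

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of a property in a test set vs background.

    ``enrichment`` is log2((b/n)/(B/N)); b = flagged genes in the test set of
    size n, B = flagged genes in the background of size N. ``direction`` is
    "up" when the test-set rate exceeds the background rate. b = 0 yields a
    negative-infinity enrichment sentinel with a still-valid p-value.
    """

    term: str | None
    b: int
    n: int
    B: int
    N: int
    enrichment: float
    p_value: float
    direction: str


@dataclass
class EdgeAnnotation:
    """DCP annotation of one integrated-network edge."""

    edge: tuple[str, str]
    dcp: str
    depth: int
    breadth: int
    score: int


def _log2_odds(b: int, n: int, B: int, N: int) -> float:
    if b == 0:
        return -math.inf
    return math.log2((b / n) / (B / N))


def _hypergeom_p(b: int, n: int, B: int, N: int, direction: str) -> float:
    """Tail probability of drawing b flagged genes in n draws from (N, B)."""
    if direction == "up":
        return float(stats.hypergeom.sf(b - 1, N, B, n))
    return float(stats.hypergeom.cdf(b, N, B, n))


def lethality_enrichment(
    test_genes: set[str],
    background_genes: set[str],
    lethal_genes: set[str],
) -> EnrichmentResult:
    """Log2-odds enrichment of lethal genes in a test set vs background.

    The p-value comes from the hypergeometric distribution over the
    background universe, taken in the direction of the observed effect.
    """
    if not test_genes <= background_genes:
        raise ValueError("test set must be a subset of the background")
    n = len(test_genes)
    N = len(background_genes)
    if n == 0 or N == 0:
        raise ValueError("empty test or background set")
    b = len(test_genes & lethal_genes)
    B = len(background_genes & lethal_genes)
    if B == 0:
        raise ValueError("background contains no lethal genes")
    direction = "up" if b / n >= B / N else "down"
    return EnrichmentResult(
        term=None,
        b=b, n=n, B=B, N=N,
        enrichment=_log2_odds(b, n, B, N),
        p_value=_hypergeom_p(b, n, B, N, direction),
        direction=direction,
    )


def term_enrichment(
    test_genes: set[str],
    background_genes: set[str],
    gene_terms: dict[str, set[str]],
    p_cutoff: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-term hypergeometric over/under-representation, uncorrected.

    Mirrors classical gene-set enrichment against a full gene universe with a
    raw p < 0.05 call and no multiple-testing correction. Terms with zero
    background annotations are skipped.
    """
    if not test_genes <= background_genes:
        raise ValueError("test set must be a subset of the background")
    terms = sorted({t for g in background_genes for t in gene_terms.get(g, ())})
    n = len(test_genes)
    N = len(background_genes)
    results: list[EnrichmentResult] = []
    for term in terms:
        annotated = {g for g in background_genes if term in gene_terms.get(g, ())}
        B = len(annotated)
        if B == 0:
            continue
        b = len(test_genes & annotated)
        direction = "up" if b / n >= B / N else "down"
        p = _hypergeom_p(b, n, B, N, direction)
        if p < p_cutoff:
            results.append(
                EnrichmentResult(
                    term=term, b=b, n=n, B=B, N=N,
                    enrichment=_log2_odds(b, n, B, N),
                    p_value=p, direction=direction,
                )
            )
    return results


def term_depths(dag: OntologyDAG) -> dict[str, int]:
    """Depth of every term: longest is_a path from a root down to the term."""
    depths: dict[str, int] = {}
    for term in nx.topological_sort(dag.graph.reverse(copy=False)):
        parents = list(dag.graph.successors(term))
        depths[term] = 0 if not parents else 1 + max(depths[p] for p in parents)
    return depths


def _min_hops_to_ancestors(dag: OntologyDAG, terms: set[str]) -> dict[str, int]:
    """Minimum upward hop count from any of ``terms`` to each ancestor."""
    hops: dict[str, int] = {}
    for t in terms:
        if t not in dag.graph:
            continue
        lengths = nx.single_source_shortest_path_length(dag.graph, t)
        for anc, d in lengths.items():
            if anc not in hops or d < hops[anc]:
                hops[anc] = d
    return hops


def deepest_common_parent(
    terms1: set[str],
    terms2: set[str],
    dag: OntologyDAG,
    depths: dict[str, int] | None = None,
    breadth_mode: str = "sum",
) -> tuple[str, int, int, int] | None:
    """Best-scoring common ancestor of two term sets.

    Returns (dcp, depth, breadth, score) with score = depth − breadth, or
    None when the sets share no ancestor. ``breadth_mode``: "sum" (default)
    adds the two endpoints' minimum hop counts; "max" takes the larger.
    """
    if depths is None:
        depths = term_depths(dag)
    hops1 = _min_hops_to_ancestors(dag, terms1)
    hops2 = _min_hops_to_ancestors(dag, terms2)
    common = set(hops1) & set(hops2)
    if not common:
        return None
    best: tuple[str, int, int, int] | None = None
    for anc in sorted(common):
        if breadth_mode == "sum":
            breadth = hops1[anc] + hops2[anc]
        else:
            breadth = max(hops1[anc], hops2[anc])
        score = depths[anc] - breadth
        # maximize score, then depth; lexicographically smallest id wins ties
        if best is None or (score, depths[anc]) > (best[3], best[1]):
            best = (anc, depths[anc], breadth, score)
    return best


def go_edge_annotate(
    network: IntegratedNetwork,
    dag: OntologyDAG,
    gene_terms: dict[str, set[str]],
    breadth_mode: str = "sum",
) -> list[EdgeAnnotation]:
    """Annotate every integrated-network edge with its DCP and score.

    Edges whose endpoints lack ontology annotation, or that share no common
    ancestor, are dropped (logged), mirroring annotation only where a common
    parent exists.
    """
    depths = term_depths(dag)
    annotations: list[EdgeAnnotation] = []
    dropped = 0
    for u, v in network.graph.edges():
        t1 = {t for t in gene_terms.get(u, ()) if t in dag.graph}
        t2 = {t for t in gene_terms.get(v, ()) if t in dag.graph}
        if not t1 or not t2:
            dropped += 1
            continue
        found = deepest_common_parent(t1, t2, dag, depths, breadth_mode)
        if found is None:
            dropped += 1
            continue
        dcp, depth, breadth, score = found
        a, b = sorted((u, v))
        annotations.append(EdgeAnnotation((a, b), dcp, depth, breadth, score))
    if dropped:
        logger.info("%d edge(s) dropped for missing annotation or common parent", dropped)
    return annotations


def rank_gateways(
    gateways: list[GatewayRecord],
    annotations: list[EdgeAnnotation],
) -> pd.DataFrame:
    """Rank gateways by the mean DCP score of their annotated incident edges.

    Returns columns (gateway, degree, mean_score) sorted by mean_score
    descending; ``degree`` counts annotated incident edges. Gateways with no
    annotated incident edge are excluded (logged).
    """
    incident: dict[str, list[int]] = {}
    for ann in annotations:
        for endpoint in ann.edge:
            incident.setdefault(endpoint, []).append(ann.score)
    rows = []
    for node in sorted({g.node for g in gateways}):
        scores = incident.get(node)
        if not scores:
            logger.info("gateway %s has no annotated incident edges, excluded", node)
            continue
        rows.append(
            {"gateway": node, "degree": len(scores),
             "mean_score": sum(scores) / len(scores)}
        )
    frame = pd.DataFrame(rows, columns=["gateway", "degree", "mean_score"])
    return frame.sort_values(
        ["mean_score", "gateway"], ascending=[False, True]
    ).reset_index(drop=True)
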