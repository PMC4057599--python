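"""Per-state correlation network construction.

One network is built per biological state: nodes are probes, and an edge is
kept for a probe pair whose Pearson correlation passes a hard threshold
(default 0.85 <= rho <= 1.00) and whose two-sided Student-t p-value is below
a cutoff (default 0.005). This hard-threshold / significance-filter scheme is
the classic construction for co-expression networks when soft thresholding is
not wanted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

SignMode = Literal["positive", "absolute"]


class ZeroVarianceError(ValueError):
    """A correlation was requested for a constant vector."""


@dataclass
class StateNetwork:
    """Thresholded correlation network for one state.

    ``graph`` is an undirected simple graph whose edges carry ``rho`` (the
    Pearson correlation) and ``p_value`` (two-sided significance). Invariants:
    no self-loops, no duplicate edges, every stored edge passed the filters in
    force when the network was built.
    """

    state_label: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors.

    Raises :class:`ZeroVarianceError` when either vector is constant, because
    the coefficient is undefined there (the pipeline skips such pairs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    rho = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    return max(-1.0, min(1.0, rho))


def correlation_p_value(rho: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation under the t transform.

    t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom; |rho| = 1
    maps to p = 0.
    """
    if n < 3:
        raise ValueError("need n >= 3 samples for a correlation p-value")
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    if abs(rho) == 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def coefficient_of_determination(rho: float) -> float:
    """R^2, the fraction of one gene's variance explained by the other."""
    return float(rho) ** 2


def complete_graph_edge_count(n: int) -> int:
    """Edge count n(n-1)/2 of the complete graph K_n over n probes."""
    return n * (n - 1) // 2


def build_state_network(
    matrix: ExpressionMatrix,
    rho_min: float = 0.85,
    p_max: float = 0.005,
    sign_mode: SignMode = "positive",
) -> StateNetwork:
    """Build the thresholded, significance-filtered network for one state.

    An edge (i, j) is kept iff the pair's correlation passes the sign rule
    (``positive``: rho >= rho_min; ``absolute``: |rho| >= rho_min) and its
    two-sided p-value is strictly below ``p_max``. Zero-variance probes are
    skipped with a warning. The result is independent of sample order and of
    the order pairs are evaluated in.
    """
    net = StateNetwork(state_label=matrix.state_label)
    net.graph.add_nodes_from(matrix.probe_ids)
    if matrix.n_probes < 2:
        logger.warning(
            "state %s: fewer than 2 probes, network has no edges", matrix.state_label
        )
        return net

    values = np.asarray(matrix.values, dtype=float)
    n = matrix.n_samples
    sd = values.std(axis=1)
    usable = sd > 0
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.warning(
            "state %s: skipping %d zero-variance probe(s)", matrix.state_label, n_skipped
        )
    idx = np.flatnonzero(usable)
    if idx.size < 2:
        return net

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(values[idx])
    corr = np.clip(corr, -1.0, 1.0)

    iu, ju = np.triu_indices(idx.size, k=1)
    rho = corr[iu, ju]
    passes = rho >= rho_min if sign_mode == "positive" else np.abs(rho) >= rho_min
    # p-values only for the survivors of the cheap threshold test
    sel = np.flatnonzero(passes)
    rho_sel = rho[sel]
    with np.errstate(divide="ignore"):
        t = rho_sel * np.sqrt((n - 2) / np.maximum(1.0 - rho_sel**2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho_sel) == 1.0] = 0.0
    keep = p < p_max

    probe_ids = np.asarray(matrix.probe_ids, dtype=object)[idx]
    for pos, k in enumerate(sel):
        if not keep[pos]:
            continue
        a = probe_ids[iu[k]]
        b = probe_ids[ju[k]]
        net.graph.add_edge(a, b, rho=float(rho[k]), p_value=float(p[pos]))
    return net
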