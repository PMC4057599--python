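"""Readers and writers for the external formats the pipeline touches.

No science lives here: faithful parsing and serialization only. Supported
formats are GEO Series Matrix text (and a bare-TSV dialect of it), SIF network
files, OBO 1.2 ontologies, MGI-style tab-delimited phenotype reports, and
two-column gene→term annotation tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

SERIES_TABLE_BEGIN = "!series_matrix_table_begin"
SERIES_TABLE_END = "!series_matrix_table_end"


class SeriesMatrixParseError(ValueError):
    """Raised when a series-matrix file lacks the expected structure."""


class SampleGroupError(KeyError):
    """Raised when a configured sample id is absent from the table header."""


@dataclass
class ExpressionMatrix:
    """Probe × sample expression table for one biological state.

    Values are kept exactly as provided (e.g. RMA-normalized log2
    intensities); no re-normalization is ever applied. After construction via
    :func:`read_series_matrix` no missing values remain.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    state_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class LethalityAnnotation:
    """Essentiality flag for one gene symbol.

    A gene is essential (lethal) iff any recorded mutant phenotype contains
    the word "lethality". Duplicate rows per gene collapse by logical OR.
    """

    gene_symbol: str
    is_lethal: bool


@dataclass
class OntologyDAG:
    """Directed acyclic term graph with child→parent ``is_a`` edges.

    ``graph`` stores one directed edge term→parent per is_a link. Obsolete
    terms are excluded at parse time. Depth is the longest is_a path from a
    root (a term with no parents) down to the term, the usual GO convention.
    """

    graph: nx.DiGraph
    roots: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        self.roots = frozenset(
            t for t in self.graph.nodes if self.graph.out_degree(t) == 0
        )

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable by following is_a links upward, incl. the term."""
        return {term} | nx.descendants(self.graph, term)


def _parse_series_table(lines: list[str]) -> pd.DataFrame:
    """Parse the tab-delimited probe × sample block of a series-matrix file."""
    header = [_dequote(c) for c in lines[0].rstrip("\n").split("\t")]
    rows = []
    index = []
    for line in lines[1:]:
        cells = line.rstrip("\n").split("\t")
        index.append(_dequote(cells[0]))
        rows.append([_dequote(c) for c in cells[1:]])
    frame = pd.DataFrame(rows, index=index, columns=header[1:])
    # empty strings are missing values; keep everything else as text so that
    # numeric round-tripping is byte-faithful until selection happens
    return frame.replace("", np.nan)


def _dequote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == '"' and token[-1] == '"':
        return token[1:-1]
    return token


def read_series_matrix(
    path: str | Path,
    sample_groups: Mapping[str, Sequence[str]],
) -> list[ExpressionMatrix]:
    """Read a GEO Series Matrix (or bare TSV) into per-state matrices.

    The file dialect is auto-detected: if the ``!series_matrix_table_begin``
    marker is present, only the block up to ``!series_matrix_table_end`` is
    read and comment lines outside it are ignored; otherwise the whole file is
    treated as a TSV whose first column holds probe identifiers.

    For each ``state_label → sample ids`` group, the columns are restricted to
    that group and every probe with a missing/blank value in those columns is
    dropped. Numeric values pass through unchanged.
    """
    path = Path(path)
    raw_lines = path.read_text().splitlines(keepends=True)
    has_begin = any(line.strip().lower().startswith(SERIES_TABLE_BEGIN) for line in raw_lines)
    if has_begin:
        table_lines: list[str] = []
        inside = False
        ended = False
        for line in raw_lines:
            stripped = line.strip().lower()
            if stripped.startswith(SERIES_TABLE_BEGIN):
                inside = True
                continue
            if stripped.startswith(SERIES_TABLE_END):
                ended = True
                break
            if inside:
                table_lines.append(line)
        if not ended:
            raise SeriesMatrixParseError(
                f"{path}: found {SERIES_TABLE_BEGIN} but no {SERIES_TABLE_END}"
            )
        if not table_lines:
            raise SeriesMatrixParseError(f"{path}: empty series-matrix table")
    else:
        table_lines = [ln for ln in raw_lines if ln.strip()]
        if not table_lines:
            raise SeriesMatrixParseError(f"{path}: empty table")

    frame = _parse_series_table(table_lines)

    matrices: list[ExpressionMatrix] = []
    for state_label, samples in sample_groups.items():
        samples = list(samples)
        missing = [s for s in samples if s not in frame.columns]
        if missing:
            raise SampleGroupError(
                f"sample ids {missing} for state {state_label!r} not in header "
                f"{list(frame.columns)}"
            )
        sub = frame[samples]
        numeric = sub.apply(pd.to_numeric, errors="coerce")
        keep = numeric.notna().all(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info(
                "state %s: dropped %d probe(s) with missing values", state_label, dropped
            )
        numeric = numeric[keep]
        matrices.append(
            ExpressionMatrix(
                probe_ids=list(numeric.index),
                sample_ids=samples,
                values=numeric.to_numpy(dtype=float),
                state_label=state_label,
            )
        )
    return matrices


def read_mgi_lethality(
    path: str | Path,
    symbol_column: int = 0,
    phenotype_column: int = 1,
    delimiter: str = "\t",
    skip_header: bool = False,
) -> set[LethalityAnnotation]:
    """Flag genes as essential from a tab-delimited phenotype report.

    A gene is lethal iff any of its rows' phenotype text contains the
    substring "lethality" (case-insensitive). Column indices are configurable
    because phenotype-report layouts vary between releases. Malformed rows are
    skipped with a warning, never fatal.
    """
    path = Path(path)
    lethal_by_gene: dict[str, bool] = {}
    needed = max(symbol_column, phenotype_column) + 1
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if skip_header and lineno == 1:
                continue
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split(delimiter)
            if len(cells) < needed:
                logger.warning("%s:%d: malformed row skipped", path, lineno)
                continue
            symbol = cells[symbol_column].strip()
            if not symbol:
                logger.warning("%s:%d: empty gene symbol skipped", path, lineno)
                continue
            lethal = "lethality" in cells[phenotype_column].lower()
            lethal_by_gene[symbol] = lethal_by_gene.get(symbol, False) or lethal
    return {LethalityAnnotation(g, flag) for g, flag in lethal_by_gene.items()}


def lethal_gene_set(annotations: Iterable[LethalityAnnotation]) -> set[str]:
    """Convenience: the symbols flagged lethal."""
    return {a.gene_symbol for a in annotations if a.is_lethal}


def read_obo(path: str | Path, include_part_of: bool = False) -> OntologyDAG:
    """Build the term DAG from an OBO 1.2 file.

    Only ``is_a`` links are used by default (``part_of`` behind a flag);
    obsolete terms are excluded. Cycles are fatal.
    """
    multi = obonet.read_obo(str(path))
    wanted = {"is_a"} | ({"part_of"} if include_part_of else set())
    dag = nx.DiGraph()
    dag.add_nodes_from(multi.nodes)
    for child, parent, rel in multi.edges(keys=True):
        if rel in wanted:
            dag.add_edge(child, parent)
    return OntologyDAG(graph=dag)


def read_gene_terms(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column gene<TAB>term annotation table into a mapping."""
    mapping: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) < 2:
            logger.warning("%s:%d: malformed annotation row skipped", path, lineno)
            continue
        mapping.setdefault(cells[0].strip(), set()).add(cells[1].strip())
    return mapping


def _edge_relation(data: dict) -> str:
    states = data.get("states")
    if states:
        if len(states) > 1:
            return "BOTH"
        return next(iter(states))
    return str(data.get("relation", "pp"))


def write_sif(network: nx.Graph, path: str | Path, state_label: str | None = None) -> None:
    """Write a network as SIF: ``nodeA<TAB>relation<TAB>nodeB`` per edge.

    The relation encodes the state label(s): the per-state label for
    single-state edges, "BOTH" for edges present in both states. Edge order is
    deterministic (lexicographic on the sorted endpoint pair).
    """
    if network.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty network")
    lines = []
    for u, v, data in network.edges(data=True):
        a, b = sorted((str(u), str(v)))
        rel = state_label if state_label is not None else _edge_relation(data)
        lines.append((a, rel, b))
    lines.sort()
    with Path(path).open("w") as fh:
        for a, rel, b in lines:
            fh.write(f"{a}\t{rel}\t{b}\n")


def read_sif(path: str | Path) -> nx.Graph:
    """Read a SIF file back into an undirected graph with a `relation` attr."""
    graph = nx.Graph()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 3:
            raise ValueError(f"malformed SIF line: {line!r}")
        a, rel, b = cells
        graph.add_edge(a, b, relation=rel)
    return graph
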