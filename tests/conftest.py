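"""Shared fixtures: toy networks, ontologies, and on-disk format samples.

All fixtures are generated programmatically so the suite needs no bundled
data files.
"""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from gatewaynet.corrnet import StateNetwork
from gatewaynet.denseclust import DenseCluster


def make_state_network(label: str, edges, nodes=()) -> StateNetwork:
    net = StateNetwork(state_label=label)
    net.graph.add_nodes_from(nodes)
    for e in edges:
        net.graph.add_edge(*e)
    return net


def clique_edges(nodes):
    return list(itertools.combinations(nodes, 2))


def make_cluster(cluster_id: str, state: str, members, network: StateNetwork) -> DenseCluster:
    members = frozenset(members)
    k = len(members)
    e = network.graph.subgraph(members).number_of_edges()
    return DenseCluster(
        cluster_id=cluster_id,
        state_label=state,
        member_nodes=members,
        density=2.0 * e / (k * (k - 1)),
    )


TOY_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root

[Term]
id: GO:0000002
name: A
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: B
is_a: GO:0000002 ! A

[Term]
id: GO:0000004
name: C
is_a: GO:0000001 ! root

[Term]
id: GO:0000005
name: gone
is_obsolete: true
"""

DIAMOND_OBO = """format-version: 1.2

[Term]
id: R:0
name: root

[Term]
id: T:B
name: B
is_a: R:0

[Term]
id: T:C
name: C
is_a: R:0

[Term]
id: T:D
name: D
is_a: T:B
is_a: T:C
"""

# root -> A -> B -> C chain used by the DCP scoring examples
CHAIN_OBO = """format-version: 1.2

[Term]
id: GO:0000010
name: root

[Term]
id: GO:0000011
name: A
is_a: GO:0000010

[Term]
id: GO:0000012
name: B
is_a: GO:0000011

[Term]
id: GO:0000013
name: C
is_a: GO:0000012
"""


@pytest.fixture
def toy_obo(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return path


@pytest.fixture
def diamond_obo(tmp_path):
    path = tmp_path / "diamond.obo"
    path.write_text(DIAMOND_OBO)
    return path


@pytest.fixture
def chain_obo(tmp_path):
    path = tmp_path / "chain.obo"
    path.write_text(CHAIN_OBO)
    return path


SERIES_MATRIX = """!Series_title\t"toy series"
!Series_platform_id\t"GPL00"
!series_matrix_table_begin
"ID_REF"\t"s1"\t"s2"\t"s3"\t"s4"
"p1"\t1.25\t2.5\t3.75\t5.0
"p2"\t2.0\t\t4.0\t6.0
"p3"\t0.5\t1.0\t1.5\t2.0
!series_matrix_table_end
"""


@pytest.fixture
def series_matrix_file(tmp_path):
    path = tmp_path / "toy_series_matrix.txt"
    path.write_text(SERIES_MATRIX)
    return path


MGI_REPORT = """Kl\tpreweaning lethality, complete penetrance
Kl\tabnormal circulating hormone level
Gait1\tabnormal gait
Emb2\tLethality, embryonic
Short\tshort row
"""


@pytest.fixture
def mgi_file(tmp_path):
    path = tmp_path / "mgi.rpt"
    # last line is deliberately malformed (one column): must be skipped
    path.write_text(MGI_REPORT.replace("Short\tshort row\n", "Short\n"))
    return path
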