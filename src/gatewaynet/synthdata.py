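"""Synthetic two-state expression data with planted modules and gateways.

Both states share one gene universe (the two correlation networks are built
over a common node set); each state has its own planted co-expression
modules. A module is driven by one latent signal: a member gene g in a
module with target pairwise correlation r is generated as

    x_g = sqrt(r) * z + sqrt(1 - r) * eps_g,

with z the module's standard-normal latent signal over that state's samples
and eps_g independent standard-normal noise, so E[corr(x_g, x_h)] = r for
any two members. Planted gateway genes belong to exactly one module per
state, so they are co-expressed with one cohort in the first state and with
an (almost) disjoint cohort in the second — the structure gateway detection
is built to find. Genes outside every module of a state are pure noise in
that state. Values are shifted/scaled to loosely mimic RMA-style log2
intensities, and everything is reproducible from the design's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io_formats import ExpressionMatrix


def _default_modules() -> dict[str, list[list[str]]]:
    yng_a = [f"g{i:03d}" for i in range(9)]
    yng_b = [f"g{i:03d}" for i in range(9, 18)]
    mid_a = [f"g{i:03d}" for i in range(18, 27)]
    mid_b = [f"g{i:03d}" for i in range(27, 36)]
    return {"YNG": [yng_a, yng_b], "MID": [mid_a, mid_b]}


@dataclass
class PlantedDesign:
    """Ground-truth layout for a two-state synthetic dataset.

    ``modules_per_state`` maps each state label to its module gene lists
    (module-exclusive members; gateways are added on top and must not appear
    in the lists). ``gateway_genes`` maps a gene to its host module index in
    each state, e.g. ``{"GW1": {"YNG": 0, "MID": 1}}`` plants GW1 in module 0
    of YNG and module 1 of MID. The planted gateway count per module pair
    must stay at or below half of either host module so the planted truth
    passes the gateway-set size restriction.
    """

    modules_per_state: dict[str, list[list[str]]] = field(default_factory=dict)
    gateway_genes: dict[str, dict[str, int]] = field(default_factory=dict)
    n_samples: int = 50
    within_module_r: float = 0.95
    background_genes: int = 60
    location: float = 8.0
    scale: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.modules_per_state:
            self.modules_per_state = _default_modules()
            if not self.gateway_genes:
                self.gateway_genes = {"GW1": {"YNG": 0, "MID": 0}}
        if not 0.0 < self.within_module_r <= 1.0:
            raise ValueError("within_module_r must lie in (0, 1]")
        if self.n_samples < 10:
            raise ValueError("need at least 10 samples per state")
        for gene, hosts in self.gateway_genes.items():
            if set(hosts) != set(self.modules_per_state):
                raise ValueError(
                    f"gateway {gene} must name exactly one host module per state"
                )
            for state, m_idx in hosts.items():
                if not 0 <= m_idx < len(self.modules_per_state[state]):
                    raise ValueError(f"gateway {gene}: no module {m_idx} in {state}")
        states = list(self.modules_per_state)
        if len(states) == 2:
            self._check_half_size_rule(*states)

    def _check_half_size_rule(self, s1: str, s2: str) -> None:
        for i, mod_i in enumerate(self.modules_per_state[s1]):
            for j, mod_j in enumerate(self.modules_per_state[s2]):
                shared = [
                    g for g, h in self.gateway_genes.items()
                    if h[s1] == i and h[s2] == j
                ]
                if not shared:
                    continue
                size_i = len(mod_i) + sum(
                    1 for h in self.gateway_genes.values() if h[s1] == i
                )
                size_j = len(mod_j) + sum(
                    1 for h in self.gateway_genes.values() if h[s2] == j
                )
                if 2 * len(shared) > min(size_i, size_j):
                    raise ValueError(
                        f"{len(shared)} planted gateways between modules "
                        f"({s1}[{i}], {s2}[{j}]) exceed half of a host module"
                    )

    @property
    def gene_universe(self) -> list[str]:
        """All genes, identical across states: module members, gateways,
        then background."""
        genes: list[str] = []
        seen: set[str] = set()
        for modules in self.modules_per_state.values():
            for module in modules:
                for g in module:
                    if g in seen:
                        raise ValueError(f"gene {g} appears in more than one module")
                    seen.add(g)
                    genes.append(g)
        for g in sorted(self.gateway_genes):
            if g in seen:
                raise ValueError(f"gateway {g} also listed as a module member")
            genes.append(g)
        genes.extend(f"BG{i:03d}" for i in range(self.background_genes))
        return genes

    def module_members(self, state: str, m_idx: int) -> frozenset[str]:
        """Planted membership of one module, gateways included."""
        members = set(self.modules_per_state[state][m_idx])
        members |= {
            g for g, h in self.gateway_genes.items() if h[state] == m_idx
        }
        return frozenset(members)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "modules_per_state": self.modules_per_state,
            "gateway_genes": self.gateway_genes,
            "n_samples": self.n_samples,
            "within_module_r": self.within_module_r,
            "background_genes": self.background_genes,
            "location": self.location,
            "scale": self.scale,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def generate_two_state(design: PlantedDesign) -> tuple[ExpressionMatrix, ...]:
    """Generate one ExpressionMatrix per state according to the design."""
    rng = np.random.default_rng(design.seed)
    r = design.within_module_r
    signal_w = np.sqrt(r)
    noise_w = np.sqrt(1.0 - r)
    genes = design.gene_universe
    gene_index = {g: k for k, g in enumerate(genes)}
    matrices = []
    for state, modules in design.modules_per_state.items():
        values = rng.standard_normal((len(genes), design.n_samples))
        latents = rng.standard_normal((len(modules), design.n_samples))
        for m_idx in range(len(modules)):
            for g in design.module_members(state, m_idx):
                row = gene_index[g]
                values[row] = signal_w * latents[m_idx] + noise_w * values[row]
        values = design.location + design.scale * values
        matrices.append(
            ExpressionMatrix(
                probe_ids=list(genes),
                sample_ids=[f"{state}_s{j:02d}" for j in range(design.n_samples)],
                values=values,
                state_label=state,
            )
        )
    return tuple(matrices)


def write_fixture(
    design: PlantedDesign,
    path: str | Path,
    dialect: str = "series_matrix",
) -> dict[str, list[str]]:
    """Write the generated matrices as one table both states share.

    ``dialect``: "series_matrix" wraps the table in GEO begin/end markers
    with quoted identifiers; "tsv" writes a bare table. Returns the
    state → sample-id grouping needed to read the file back. The design is
    serialized alongside (``<path>.design.yaml``) for provenance.
    """
    matrices = generate_two_state(design)
    all_samples = [s for m in matrices for s in m.sample_ids]
    genes = matrices[0].probe_ids
    path = Path(path)
    quote = dialect == "series_matrix"

    def fmt(cell: str) -> str:
        return f'"{cell}"' if quote else cell

    with path.open("w") as fh:
        if dialect == "series_matrix":
            fh.write('!Series_title\t"synthetic two-state fixture"\n')
            fh.write("!series_matrix_table_begin\n")
        fh.write("\t".join([fmt("ID_REF")] + [fmt(s) for s in all_samples]) + "\n")
        for gi, gene in enumerate(genes):
            row = [fmt(gene)]
            for m in matrices:
                row.extend(f"{v:.6f}" for v in m.values[gi])
            fh.write("\t".join(row) + "\n")
        if dialect == "series_matrix":
            fh.write("!series_matrix_table_end\n")
    design.to_yaml(str(path) + ".design.yaml")
    return {m.state_label: list(m.sample_ids) for m in matrices}
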