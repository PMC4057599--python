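# Methods

## Model and assumptions

The pipeline models each biological state as an undirected correlation
network over one shared probe set: nodes are probes (redundant probes for a
gene are deliberately kept), and an edge joins two probes whose expression
vectors are strongly, significantly correlated within that state. The
underlying assumptions are the usual ones for hard-thresholded
co-expression networks: expression values arrive normalized (e.g. RMA log2
intensities) and are used as given; linear (Pearson) association is the
relevant signal; and a hard threshold plus a significance filter — rather
than soft thresholding — is acceptable because downstream analysis needs
discrete dense clusters, not weighted topology.

Gateway analysis then rests on an empirical observation about two-state
networks: dense clusters of different states rarely share more than a few
nodes. A shared node (a *gateway*) necessarily routes every path between
its two host clusters in the integrated graph, so the gateway set
S = V(X) ∩ V(Y) is a node cut set between clusters X and Y, and the
per-node share of cluster-bridging edges (*gatewayness*) measures how much
of the state transition a single gene accounts for.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `rho_min` | 0.85 | lower Pearson bound; R² = 0.7225, so ≥72% of one gene's variance is ascribed to the other |
| `p_max` | 0.005 | two-sided Student-t significance cutoff on each correlation; edges are kept iff p < p_max |
| `sign_mode` | `positive` | literal 0.85 ≤ ρ ≤ 1.00 range; `absolute` admits anticorrelation for the commoner ± convention |
| `degree_cutoff` | 4 | MCODE scoring ignores nodes of degree < 4 |
| `k_core` | 4 | grown sets must contain a 4-core, eliminating K₃ and anything below 5 nodes |
| `node_score_cutoff` | 0.2 | growth admits neighbors scoring ≥ 80% of the seed score |
| density thresholds | 0.65 / 0.75 / 0.85 | cluster retention bars; gateway sets are nested as the bar rises |
| ER null | n = 12300, p = 10/10000 | size-matched structureless reference |
| scale-free null | exponent 2.5 | hub-containing reference, edge count matched to the real networks |

The p-value direction deserves a note: correlations are kept when
p < 0.005, the conventional keep-if-significant reading.

## Clustering

MCODE is reimplemented from its published description: each node is scored
by (highest k-core order of its closed neighborhood) × (density of that
core); clusters grow outward from unvisited seeds in descending score
order, admitting unvisited neighbors within the score threshold; haircut
(iterated removal of members with fewer than two in-cluster connections) is
on and fluff is off; grown sets without a `k_core`-core are discarded. Ties
in seed order break lexicographically by probe id, making the output
deterministic. One documented consequence of faithful seeded growth: two
equally dense regions joined by a bridge edge grow into a single cluster
(all node scores are equal, so growth crosses the bridge). Such
over-predicted unions have low density and are removed by the 65% density
filter, consistent with MCODE's known tendency to over-predict cluster
size while finding dense regions accurately.

## Gatewayness bookkeeping

The numerator e(s) counts integrated-graph edges of either state joining s
to (V(X) ∪ V(Y)) \ S; the denominator is the sum of e(s′) over the gateway
set. Edges between two gateways are excluded — they connect gateway to
gateway, not cluster to gateway. This bookkeeping makes a sole gateway
score exactly 1.00 and makes scores sum to 1 per cluster pair. The size
restriction is implemented as |S| ≤ min(|V(X)|, |V(Y)|)/2 (the ≤ reading of
"half the size of either"), which also excludes the trivial case
V(X) = V(Y) = S.

A node bridging several qualifying cluster pairs yields one record per
pair; `max_gatewayness_per_node` provides the single-value-per-node summary
(maximum over pairs) used for compact tables.

## Null models

Null analysis treats a pair of simulated networks over one shared node set
as the two states, with density requirements not enforced. G(12300, 0.001)
draws contain no 4-core clusters, so each network's full node set is
treated as one whole-network cluster and the size restriction is suspended
— then S is the entire node set and every node is a gateway. In that
degenerate case (V(X) ∪ V(Y)) \ S is empty and the literal e(s) would be
zero for all nodes, so e(s) falls back to counting all integrated-graph
edges incident to s; each node's score is its degree share, a near-uniform
null distribution whose values sum to 1. This convention is the package's
own resolution of an under-determined corner of the procedure; the gateway
*count* (every shared node) does not depend on it. Scale-free nulls use
the static power-law model (degree exponent 2.5, edge count matched to a
target network) via igraph. Observed-vs-null comparison uses the classical
pooled-variance two-sample t-test ("student's t-test" taken literally),
with stars at p < 0.05 (*) and p < 0.0005 (***).

## Ontology edge annotation

Term depth is the longest is_a path from a root (the usual GO depth
convention; a shortest-path variant is not provided because depth feeds a
maximization and the longest-path reading keeps deep annotations deep).
Breadth is the sum over the two endpoints of the minimum hop count from the
endpoint's term set up to the candidate ancestor; a `breadth_mode="max"`
alternative exists because "how far the nodes are apart" is ambiguous
between sum and max — sum is the default as it penalizes both detours
additively, matching the additive form of score = depth − breadth. The DCP
maximizes the final score (not raw depth), so the reported score is the
best achievable for the edge; ties break toward the deeper term, then the
lexicographically smaller id. Only is_a links build the DAG by default
(part_of behind a flag). Gateway ranking averages the signed scores of
annotated incident edges — the mean can be negative when a gateway's
neighbors only meet near the ontology root.

Enrichment layers use the hypergeometric distribution in the direction of
the observed effect and apply **no** multiple-testing correction: the term
enrichment is deliberately a raw p < 0.05 screen, so about 5% of null terms
are expected to appear by chance; treat its output as a shortlist, not an
inference.

## Synthetic data

The generator emulates exactly the structure the method assumes: one gene
universe shared by both states, per-state dense modules driven by a single
latent factor (member g is √r·z + √(1−r)·ε, giving expected pairwise
correlation r analytically), gateway genes loading on one host module per
state, and pure-noise background genes. Defaults — two modules of 9
exclusive members per state plus one planted gateway, r = 0.95, 50 samples
per state, 60 background genes, values scaled to an RMA-like
location 8 / scale 1.5 — were chosen once as a realistic "very highly
co-expressed module" regime for a 0.85 hard threshold; with these settings
the full pipeline recovers exactly the planted gateway with gatewayness
1.00 in ≥95% of seeds. What the generator does *not* emulate: probe-level
microarray artifacts, batch effects, heavy-tailed expression noise,
correlated background structure, or weakly-correlated modules near the
threshold. Passing tests therefore demonstrate correctness of the
machinery on clean planted structure, not robustness of the biology on
real arrays.

## Numerical and design choices

- Correlations are computed vectorized (`numpy.corrcoef`) and clipped to
  [−1, 1]; |ρ| = 1 maps to p = 0 directly. Zero-variance probes are
  skipped with a warning, not errors.
- Networks are invariant to sample order and pair-evaluation order; edge
  and cluster outputs are deterministic given the input and parameters
  (lexicographic tie-breaks throughout).
- Cluster pairs whose gateways carry no cross edges are dropped with a
  warning (degenerate pairs); within-state cluster pairs are never
  compared.
- The series-matrix reader auto-detects GEO marker-delimited files versus
  bare TSV and never alters numeric values; probes with a missing value in
  the selected columns are dropped per state.
- MGI-style lethality flags use case-insensitive substring matching on
  "lethality" with configurable column indices, since report layouts vary.
- All CLI randomness flows from one top-level seed expanded per stage.

## Problem sizes

The test suite and the acceptance script run at the sizes the method
defines where those are cheap (the 12,300-node ER null runs in about half
a minute) and at desk scale elsewhere: planted-recovery statistics use 20
seeds of the default ~100-probe design, and the scale-free exponent check
uses two replicate draws at n = 12300 with a Clauset-style tail MLE
(d ≥ 15), which sits within 0.3 of the requested exponent at this density.

## Known limitations

- Cluster boundaries from any MCODE reimplementation can differ from the
  AllegroMCODE plugin's on real data, and gateway counts downstream are
  sensitive to those boundaries.
- Gatewayness is defined for exactly two states; multi-state
  generalization is out of scope.
- The scale-free null's gateway count is seed- and clustering-dependent
  and is reported, not asserted.
- No multiple-testing correction anywhere (by design, see above), and no
  soft-thresholding / topological-overlap network construction.
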