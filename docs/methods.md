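# Methods

This note records the models, parameter defaults and numerical choices
behind `dinet`, and what the synthetic fixtures do and do not establish
about real data.

## Data model and input conventions

A background knowledge network is a set of uniquely identified nodes and
typed edges (activation, inhibition, binding, unknown; directed or not).
Measurement tables are wide: one `<label>_logFC` / `<label>_padj` column
pair per condition after the `geneID` column. Significance values must lie
in [0, 1]; weights are unrestricted signed reals. Identifier consistency
between network and measurements is checked by `validate_network`;
measured identifiers absent from the network are reported and excluded
from analysis rather than failing the run, since measurement tables
routinely cover more genes than a curated network.

Tables may be tab-, comma- or semicolon-separated (auto-detected from the
header; a header with none of the three is treated as a single-column
table). Encoding is UTF-8 with decimal points. GraphML attributes follow
the same column names (`shortName`, `annotation`, `bin`, `clusterID`,
`x`, `y`, `degree`); the mapping is overridable per call because
Cytoscape and yEd exports differ. XGMML is read only for coordinates, and
when both GraphML and XGMML carry coordinates the XGMML wins — an
interpretation we fixed because the two sources are otherwise ambiguous;
the merge report lists what was and was not matched.

## Pre-processing

Simplification removes self-loops and duplicate edges. A duplicate is an
edge with the same (source, target, interaction type), with direction
respected for directed edges and endpoint order ignored for undirected
ones; the first occurrence is kept. This deliberately preserves reciprocal
directed regulation (A→B and B→A) and parallel edges of different type
(e.g. a pair both binding and activating), which a blunt multigraph
collapse would destroy. Degrees are incident-edge counts on the simplified
graph, ignoring direction, so the degree sum equals twice the edge count.

Default layout is a row-major square grid over lexicographically sorted
node identifiers (side ⌈√n⌉) refined by Kamada–Kawai. Kamada–Kawai as
implemented here is a deterministic quasi-Newton optimisation from a fixed
start, so no seed is needed for reproducibility; user-supplied coordinates
are restored verbatim after refinement and are never moved.

## Clustering pipeline

Community detection is multi-level modularity optimisation (Louvain) on
the undirected simple view, via python-igraph. python-igraph draws its
randomness from Python's `random` module, so seeding `random` makes both
Louvain and spinglass reproducible; the seed is part of
`ClusteringParams` and of every settings log. Communities with fewer than
`min_cluster_size = 5` nodes are dropped before classification — for
clusters of borderline size the drop therefore happens first, an ordering
we fixed because tiny fragments are not meaningfully classifiable.
Cluster numbering is by decreasing size with ties broken by smallest
member identifier, so outputs are byte-stable under a fixed seed.

Classification uses three structural archetypes with explicit tolerances,
since "approximately" needs a number:

* **densely connected** — directed arc count ≥ (1 − 0.10) · n(n−1), with
  undirected edges counting twice, so an undirected clique with
  n(n−1)/2 edges qualifies. The 10 % tolerance is configurable
  (`dense_tolerance`); n ≥ 2 required.
* **star-like** — exactly one hub (degree ≥ `hub_fraction = 0.60` of the
  cluster maximum, boundary inclusive), |edges − n| ≤ max(2, 0.10·n), hub
  closeness maximal in the cluster, and hub betweenness in the undirected
  view within 10 % of (n−1)(n−2)/2 — the exact hub betweenness of a pure
  star, against which the implementation is tested by brute-force path
  counting for n = 4..12.
* **small / regular** — everything else, split by the sub-division gate.

The sub-division gate excludes densely connected and star-like clusters
and those below 2¹⁰ nodes **and** 2¹¹ edges; we read the exclusion as a
logical AND (both below ⇒ too small to be worth splitting), with an OR
reading available through `gate_logic` since the conjunction is a genuine
ambiguity. Eligible clusters are subdivided by spinglass with the spin
count set to the cluster's hub count. Spinglass is undefined on
disconnected graphs, so a disconnected eligible cluster is handled per
component with spins allocated proportionally to each component's share of
hubs (minimum one, capped at component size). Sub-clusters carry
hierarchical labels (`7.1`, `7.2`, …); a flat integer renumbering is used
in exported tables.

Per-cluster layout starts from the deterministic grid and refines with
Fruchterman–Reingold when the cluster has ≤ 2⁶ nodes and ≤ 2⁶ edges
(boundary inclusive) and Kamada–Kawai otherwise; the chosen algorithm is
recorded per cluster. Fruchterman–Reingold is seeded explicitly.

## Differential networks

The activity rule follows the stated inequalities exactly: significance
strictly below α, absolute weight at or above the cut-off (so a node at
exactly |logFC| = 0.5 with the default threshold passes, and one at
exactly p = 0.05 fails). Missing measurements never pass — absence of
evidence is not significance. The edge weight formula and its properties
(range [0, 1], sub-unit additivity, saturation, symmetry) are given in the
README; non-finite inputs are rejected.

The minimum-degree display filter uses the node's degree in the
*background* cluster, not in the differential network, so it is a stable
cluster-level filter that does not cascade as nodes drop out. The
module-size guard accepts 2 to 16 384 loop-free edges, both bounds
inclusive ("between" over discrete counts).

Functional-bin enrichment expands hierarchical bin codes to all ancestors
(`17.5.1` counts for `17` and `17.5`), computes the one-sided
hypergeometric upper tail per bin (cluster vs whole network) and adjusts
with Benjamini–Hochberg across the bins tested within the cluster. The
test choice is ours — the field standard for categorical
over-representation — as no particular test is prescribed by the workflow
the package implements.

## Dynamics

Interpolation is the straight-line homotopy `(1−u)·v0 + u·v1`; higher-order
easing is out of scope. Three rules govern elements that change status
across a transition:

* a node measured at both endpoints interpolates between its measured
  weights, whether or not it passes at either end — visibility is decided
  frame by frame;
* a node measured at only one endpoint ramps from/to zero;
* significance is not interpolated: frames with u < 0.5 inherit the
  source condition's significance pass/fail and frames with u ≥ 0.5 the
  destination's (`significance_rule="nearest"`, the default), or both can
  be required (`"both"`). This is an interpretation — only weights are
  meaningfully continuous between conditions.

Frames at integer t are built directly from the endpoint condition, so
endpoint fidelity is exact to the bit, not within a tolerance.

Rendering writes SVG with a pinned hash salt and no timestamp metadata, so
the same frame renders to byte-identical files. Edge styling: activation
full line with a single arrowhead, inhibition full line with a terminal
bar, binding dashed with arrowheads at both ends.

The settings log records tool version, input paths with SHA-256 checksums,
every threshold and seed, and the output checksum. `replay` re-executes
the pipeline from the log; a changed input or parameter surfaces as a
checksum mismatch, and missing inputs are listed. Exported frames use a
self-describing tab-separated schema (one record per element per frame)
rather than a video container, to stay toolchain-neutral.

## Synthetic fixtures

`generate_background` plants clusters of known topology — cliques
(exactly n(n−1)/2 undirected edges), stars (one hub, n−1 spokes), sparse
directed random blocks — joined by a small number of bridges, with ground
truth labels and planted classifications. `generate_measurements` models
transcriptional switches: per condition a responsive set whose members
draw |logFC| from a shifted folded normal (location 1.0, spread 0.5 — above
the default 0.5 cut-off so thresholds are informative), balanced random
signs, and significance uniform on (0, 0.01); non-responsive nodes draw
weight from N(0, 0.1) and significance uniform on (0, 1). A persistence
probability (default 0.7) carries responsive nodes between consecutive
conditions, topping the set back up to the target fraction (default 0.3),
which produces the on/off module dynamics the animation machinery
displays. Default fixture sizes (tens of nodes per cluster, three
communities for recovery tests) keep each test comfortably in the
sub-minute range while remaining large enough for community detection to
be non-trivial.

What the fixtures do **not** emulate: microarray/RNA-seq noise structure,
probe-level effects, correlated significance across neighbouring genes, or
realistic degree distributions of curated networks. Passing tests
establish the pipeline's algorithmic correctness and determinism, not
recovery performance on real networks, where community structure is far
less separable than in the planted fixtures.

The worked toy is a fixed 12-node, two-cluster, three-condition instance
with hand-written constants, used for golden and endpoint-fidelity checks;
it exercises all three interaction types and a cross-cluster bridge.

## Known limitations

* Community detection quality is whatever Louvain/spinglass deliver;
  stochastic variation across seeds means a specific decomposition of a
  specific large network is not a contract, only seeded determinism is.
* The star/dense tolerances (10 %) are pragmatic defaults, configurable
  but not fitted to any corpus of curated networks.
* No identifier translation across species or orthologue groups; input
  identifiers must already match.
* No SBML/SIF/BioPAX import; XGMML is coordinates-only.
* Rendering is static SVG; interactive widgets and movie encoding are out
  of scope.
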