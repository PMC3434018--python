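# Methods

This note records the model implemented by `procgraph`, the parameters
that matter, the numerical and design choices made where the procedure
admitted more than one reading, and what the synthetic benchmark does
and does not demonstrate.

## Model and assumptions

The pipeline assumes that (i) proteins contributing to the same
function are more densely inter-connected with each other than with the
rest of the network (functional modules overlap topological modules),
(ii) PPI evidence is transitive within a function node, and (iii) a
dependence between two functions that is mediated by a third function
must not be drawn as a direct edge (the markov property). Everything
else follows from those three commitments: topology (k-cliques and
clique-percolation communities) arbitrates which of a protein's several
annotations reflect direct participation, and edge criteria are
deliberately conservative so that single-witness evidence never creates
a functional dependence.

The two scores:

- **PMS** (protein membership score) for protein p in node FN is the
  best agreement between FN and any cluster containing p, scored as the
  2×2 contingency "accuracy" `100·(a+d)/N` over the N network proteins,
  where `a = |FN ∩ C|` and `d = |FNᶜ ∩ Cᶜ|`. This form rewards both
  co-inclusion and co-exclusion and is bounded in [0, 100]. A `literal`
  variant with denominator `a + |FNᶜ∩C| + 2·|FNᶜ∩Cᶜ|` is provided for
  audit.
- **NTS** (node topological score) is the best cluster overlap of the
  node, scored as Jaccard similarity `100·|FN ∩ C| / |FN ∪ C|` — the
  canonical similarity between two sets, independent of proteins
  unrelated to either. A `literal` variant with denominator
  `|FN∩C| + |FN∩Cᶜ| + |FNᶜ∩Cᶜ|` (evaluated over the union of all
  cluster members and the node) is likewise available.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `pms_threshold` | 95 % | membership kept despite a better-scoring node elsewhere if PMS ≥ threshold |
| `nts_threshold` | 0 % | reduction threshold; 0 keeps every node, sweeps locate the knee |
| `k_min`, `k_max` | 3, `auto` | clique orders scanned; `auto` = largest clique present |
| `membership_mode` | `per_protein` | compare a protein's PMS across the nodes containing it; `per_node` compares members within one node |
| `edge_crossing_policy` | `binary_only` | only direct-contact (binary-assay) crossings qualify as edge evidence; `any_assay` counts all |
| `include_parent_seeding` | on | terms shared only at the parent level also seed nodes |

The 95 % default reflects that a membership should survive competition
only when its own cluster agreement is nearly perfect. `per_protein` is
the semantics illustrated by the method's motivating example (a doubly
annotated protein is retained in the node that best overlaps the clique
containing it); `per_node` reproduces a stricter within-node reading
and is kept as a variant. The cluster set deliberately contains both
bare k-cliques and their percolation communities, for every k in range:
both pattern kinds carry signal and deduplication is by
(kind, k, member set).

## Edge semantics

An edge requires strictly more than one witness: > 1 shared protein or
> 1 qualifying crossing PPI. A PPI whose endpoints lie together inside
any single function node is an *internal* PPI — it was consumed in
defining that node — and never counts as crossing evidence for any
other pair of nodes. Without this exclusion, the internal wiring of a
mediating node B (whose content overlaps both A and C) would manufacture
direct A–C evidence and systematically violate the markov property the
graph is built to respect.

The `baseline` mode (used by `procgraph compare`) is the permissive
contrast: no PMS pruning, no enucleation, and an edge for any single
shared protein or crossing PPI of any assay class. Every default-mode
edge is also a baseline edge.

## Deterministic order and degenerate inputs

- Enucleation runs to a fixpoint over passes in descending protein-set
  size, ties broken by lexicographic node id, so cascaded subtractions
  are reproducible. Merging and enucleation alternate until neither
  changes anything, since subtraction can create new identical sets.
- Nodes falling below two proteins at any stage are discarded (a
  function node is defined by an internal PPI between at least two
  proteins).
- Term depth is the longest directed path to a root (the conventional
  specificity reading under multiple parents); a shortest-path variant
  is selectable.
- An empty cluster set yields PMS = NTS = 0 everywhere; refinement then
  removes nothing (every protein's scores tie at 0).
- Empty networks produce empty process graphs, and writers emit valid
  empty documents. All exports order nodes and edges canonically, so a
  given graph serializes byte-identically.
- Node ids take the numeric part of the seeding term id (so
  `GO:0045046` becomes node `45046`); merged nodes join the ids of
  their retained labels with `+`.

## Synthetic benchmark

The generator plants a chain of protein modules, wires each internally
with probability `p_in` and the background with `p_out`, shares
`mediator_overlap` proteins between consecutive modules, and adds two
guaranteed binary contacts per consecutive pair, routed through proteins
exclusive to each module so the contact is evidence for that pair only.
Each module's proteins are annotated with a leaf term on a private
ontology branch; noise annotations are drawn half from ancestors of the
true term (exercising the specificity filter) and half from a random
other module's term (exercising PMS pruning). All randomness flows from
one `numpy` generator seeded by the model.

Defaults (module sizes 6/8/10, `p_in` 0.9, `p_out` 0.02, overlap 2,
noise rate 0.1, binary fraction 0.42) describe a small, realistically
noisy benchmark; the binary fraction matches the share of direct-contact
assays typical of curated interactomes.

What passing these benchmarks shows: the pipeline recovers planted
modules, links exactly the consecutive pairs, and leaves mediated pairs
unlinked, under clean and moderately noisy conditions. What it does not
show: performance on real interactomes, whose annotation errors are not
independent, whose module sizes and overlaps are heterogeneous, and
whose assay coverage is biased by study effort. Published graph sizes
for real yeast domains additionally depend on database versions and on
unstated clique-order choices, so they are not reproduction targets.

A known trade-off is visible in small chains: PMS pruning can remove a
mediator protein from one of the two modules sharing it, lowering
content recovery slightly (best-match Jaccard below 1) while improving
edge precision and mediation compliance — the score prioritizes
non-redundant assignment over complete coverage by design.

## Limitations

- Clique enumeration is exponential in the worst case; the intended
  scale is domain-restricted networks (hundreds of proteins), not whole
  interactomes.
- Edge directions are never inferred; they are accepted only as
  user-supplied annotations tagged with an expert-judgment rule (1–6).
- Node relabeling to biologically adapted names is a curation step; the
  package stores user-supplied display labels only.
- Only `is_a`/`part_of` hierarchy relations are honored by default;
  richer OBO semantics (e.g. `regulates`) are out of scope.
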