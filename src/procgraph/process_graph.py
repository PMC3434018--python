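"""The core pipeline: from an annotated PPI network to a process graph.

A *function node* (FN) is a set of at least two interacting proteins
sharing a functional annotation; the *process graph* (PG) links FNs whose
mutual dependence is supported by shared proteins or by crossing PPI.
The pipeline enforces non-redundant protein-to-function assignment so
that the PG approaches the markov property: all information about a
function is carried by its graph neighbors, and dependencies mediated by
an intermediate function must not receive a direct edge.

Stages
------
1.  reduce each protein's annotations to the most specific terms;
2.  seed one FN per term shared (directly, or through a common parent
    term) by at least two interacting proteins;
3.  refine memberships with the protein membership score (PMS): a
    protein stays only in the FNs that best overlap the k-clique /
    community clusters it belongs to, unless its score clears a
    satisfaction threshold (default 95%);
4.  merge FNs with identical protein content (keeping the deepest
    labels) and enucleate FNs that are proper subsets of others;
5.  link FN pairs sharing >1 protein or >1 qualifying crossing PPI
    (binary-assay crossings only, by default);
6.  score each FN with the node topological score (NTS, best cluster
    overlap) and drop nodes below the NTS threshold.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .ontology import OntologyDAG, filter_known_terms
from .topology import BINARY, ClusterSet, PPINetwork, build_cluster_set

logger = logging.getLogger(__name__)

SIMPLE_MATCHING = "simple_matching"
LITERAL = "literal"
JACCARD = "jaccard"

_NUMERIC_ID = re.compile(r"^[A-Za-z_]+:0*(\d+)$")


def term_node_id(term_id: str) -> str:
    """Node id from the numeric part of a term id ("GO:0045046" -> "45046")."""
    m = _NUMERIC_ID.match(term_id)
    return m.group(1) if m else term_id


# -- data types ----------------------------------------------------------


@dataclass
class FunctionNode:
    """A labeled set of proteins with score and provenance history."""

    node_id: str
    labels: frozenset[str]
    proteins: set[str]
    nts: float | None = None
    core_fraction: float | None = None
    history: list[tuple] = field(default_factory=list)
    pms: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "FunctionNode":
        return FunctionNode(
            self.node_id,
            self.labels,
            set(self.proteins),
            self.nts,
            self.core_fraction,
            list(self.history),
            dict(self.pms),
        )


@dataclass(frozen=True)
class EdgeDirection:
    """User-supplied causal orientation of a PG edge; never inferred."""

    from_id: str
    to_id: str
    rule: int  # expert-judgment rule tag, 1..6
    note: str = ""

    def __post_init__(self):
        if self.rule not in range(1, 7):
            raise ValueError(f"direction rule tag must be in 1..6, got {self.rule}")


@dataclass
class PGEdge:
    """Undirected FN-FN edge with its supporting evidence counters."""

    u: str
    v: str
    shared_protein_count: int = 0
    crossing_binary_ppi_count: int = 0
    crossing_total_ppi_count: int = 0
    direction: EdgeDirection | None = None

    def __post_init__(self):
        if self.u == self.v:
            raise ValueError("self-edges are not allowed in a process graph")
        if self.u > self.v:
            self.u, self.v = self.v, self.u

    @property
    def key(self) -> tuple[str, str]:
        return (self.u, self.v)


class ProcessGraph:
    """FNs plus evidence-bearing undirected edges."""

    def __init__(self, nodes: Iterable[FunctionNode] = (), edges: Iterable[PGEdge] = ()):
        self.nodes: dict[str, FunctionNode] = {}
        self.edges: dict[tuple[str, str], PGEdge] = {}
        for n in nodes:
            self.add_node(n)
        for e in edges:
            self.add_edge(e)

    def add_node(self, node: FunctionNode) -> None:
        if node.node_id in self.nodes:
            raise ValueError(f"duplicate node id {node.node_id!r}")
        self.nodes[node.node_id] = node

    def add_edge(self, edge: PGEdge) -> None:
        if edge.u not in self.nodes or edge.v not in self.nodes:
            raise ValueError(f"edge {edge.key} references unknown node")
        self.edges[edge.key] = edge

    def has_edge(self, a: str, b: str) -> bool:
        return (min(a, b), max(a, b)) in self.edges

    def neighbors(self, node_id: str) -> list[str]:
        out = []
        for u, v in self.edges:
            if u == node_id:
                out.append(v)
            elif v == node_id:
                out.append(u)
        return sorted(out)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_nodes(self) -> list[FunctionNode]:
        return [self.nodes[k] for k in sorted(self.nodes)]

    def sorted_edges(self) -> list[PGEdge]:
        return [self.edges[k] for k in sorted(self.edges)]


@dataclass
class PipelineConfig:
    """Tunable behaviour of the pipeline; defaults follow the method text."""

    pms_threshold: float = 95.0
    nts_threshold: float = 0.0
    k_min: int = 3
    k_max: int | str = "auto"
    membership_mode: str = "per_protein"  # or "per_node" (literal pseudocode)
    pms_formula: str = SIMPLE_MATCHING  # or "literal"
    nts_formula: str = JACCARD  # or "literal"
    edge_crossing_policy: str = "binary_only"  # or "any_assay"
    include_parent_seeding: bool = True
    parent_specificity_filter: bool = False
    seed: int = 0  # reserved; the default pipeline is fully deterministic

    def __post_init__(self):
        if not 0 <= self.pms_threshold <= 100:
            raise ValueError("pms_threshold must be in [0, 100]")
        if not 0 <= self.nts_threshold <= 100:
            raise ValueError("nts_threshold must be in [0, 100]")
        if self.k_min < 3:
            raise ValueError("k_min must be >= 3")
        if self.membership_mode not in ("per_protein", "per_node"):
            raise ValueError(f"bad membership_mode {self.membership_mode!r}")
        if self.pms_formula not in (SIMPLE_MATCHING, LITERAL):
            raise ValueError(f"bad pms_formula {self.pms_formula!r}")
        if self.nts_formula not in (JACCARD, LITERAL):
            raise ValueError(f"bad nts_formula {self.nts_formula!r}")
        if self.edge_crossing_policy not in ("binary_only", "any_assay"):
            raise ValueError(f"bad edge_crossing_policy {self.edge_crossing_policy!r}")


# -- stage: FN seeding ---------------------------------------------------


def seed_function_nodes(
    net: PPINetwork,
    annmap: Mapping[str, Iterable[str]],
    dag: OntologyDAG,
    include_parent_seeding: bool = True,
) -> list[FunctionNode]:
    """Create one FN per term shared by interacting protein pairs.

    ``annmap`` must already hold most-specific annotation sets.  For each
    interacting pair (v, w) every term in annot_v ∩ annot_w — plus, when
    parent seeding is on, every term in pa(annot_v) ∩ pa(annot_w) — gains
    a FN containing both proteins.
    """
    missing = sorted(set(annmap) - net.proteins)
    if missing:
        logger.warning(
            "%d annotated protein(s) absent from the network, ignored: %s",
            len(missing),
            ", ".join(missing[:5]),
        )
    fns: dict[str, FunctionNode] = {}
    parent_cache: dict[frozenset, frozenset] = {}

    def parent_union(terms: frozenset[str]) -> frozenset[str]:
        cached = parent_cache.get(terms)
        if cached is None:
            out: set[str] = set()
            for t in terms:
                out |= dag.parents(t)
            cached = frozenset(out)
            parent_cache[terms] = cached
        return cached

    for v, w, _assays, _classes in net.interactions():
        av = frozenset(annmap.get(v, ()))
        aw = frozenset(annmap.get(w, ()))
        if not av or not aw:
            continue
        shared = set(av & aw)
        if include_parent_seeding:
            shared |= parent_union(av) & parent_union(aw)
        for term in shared:
            fn = fns.get(term)
            if fn is None:
                fn = FunctionNode(
                    node_id=term_node_id(term),
                    labels=frozenset([term]),
                    proteins=set(),
                    history=[("seeded", term)],
                )
                fns[term] = fn
            fn.proteins.update((v, w))
    # term-keyed node ids can collide only if two distinct terms share a
    # numeric part; fall back to the raw term id in that case
    by_id: dict[str, str] = {}
    for term, fn in fns.items():
        if fn.node_id in by_id and by_id[fn.node_id] != term:
            fn.node_id = term
        by_id[fn.node_id] = term
    return [fns[t] for t in sorted(fns, key=lambda t: fns[t].node_id)]


# -- stage: PMS refinement -----------------------------------------------


def _match_score(
    fn_proteins: frozenset[str] | set[str],
    cluster_members: frozenset[str],
    universe: frozenset[str],
    formula: str,
) -> float:
    a = len(fn_proteins & cluster_members)  # in FN and in cluster
    d = len(universe) - len(fn_proteins | cluster_members)  # in neither
    if formula == SIMPLE_MATCHING:
        n = len(universe)
        return 100.0 * (a + d) / n if n else 0.0
    elif formula == LITERAL:
        # denominator exactly as printed: a + |FN^c ∩ C| + 2·|FN^c ∩ C^c|
        c = len(cluster_members - set(fn_proteins))
        denom = a + c + 2 * d
        return 100.0 * (a + d) / denom if denom else 0.0
    raise ValueError(f"unknown PMS formula {formula!r}")


def pms(
    protein_id: str,
    fn: FunctionNode,
    clusters: ClusterSet,
    universe: Iterable[str],
    formula: str = SIMPLE_MATCHING,
) -> float:
    """Protein membership score: best match between the FN and any
    topological cluster containing the protein (0 if it belongs to none)."""
    if protein_id not in fn.proteins:
        raise ValueError(f"protein {protein_id!r} is not a member of FN {fn.node_id!r}")
    universe = frozenset(universe)
    best = 0.0
    for cluster in clusters.containing(protein_id):
        best = max(best, _match_score(fn.proteins, cluster.members, universe, formula))
    return best


def refine_by_pms(
    fns: Sequence[FunctionNode],
    clusters: ClusterSet,
    universe: Iterable[str],
    cfg: PipelineConfig,
) -> list[FunctionNode]:
    """Prune implausible memberships by PMS (two-phase: score, then prune).

    ``per_protein`` mode (default) compares a protein's scores across the
    FNs containing it and drops it from every FN where it scores below
    both its own maximum and the threshold.  ``per_node`` mode compares,
    within each FN, each member against the FN's best-scoring member.
    FNs left with fewer than two proteins are discarded.
    """
    universe = frozenset(universe)
    scores: dict[tuple[int, str], float] = {}
    for i, fn in enumerate(fns):
        for p in fn.proteins:
            scores[(i, p)] = pms(p, fn, clusters, universe, cfg.pms_formula)

    removals: list[tuple[int, str, float]] = []
    if cfg.membership_mode == "per_protein":
        best_of: dict[str, float] = {}
        for (i, p), s in scores.items():
            best_of[p] = max(best_of.get(p, 0.0), s)
        for (i, p), s in scores.items():
            if s < best_of[p] and s < cfg.pms_threshold:
                removals.append((i, p, s))
    else:  # per_node: literal pseudocode semantics
        for i, fn in enumerate(fns):
            node_best = max((scores[(i, p)] for p in fn.proteins), default=0.0)
            for p in fn.proteins:
                s = scores[(i, p)]
                if s < node_best and s < cfg.pms_threshold:
                    removals.append((i, p, s))

    out: list[FunctionNode] = []
    refined = [fn.copy() for fn in fns]
    for i, p, s in removals:
        refined[i].proteins.discard(p)
        refined[i].history.append(("pms-pruned", p, round(s, 6)))
    for i, fn in enumerate(refined):
        fn.pms = {p: scores[(i, p)] for p in fn.proteins}
        if len(fn.proteins) >= 2:
            out.append(fn)
        else:
            logger.info("FN %s dropped after PMS refinement (<2 proteins)", fn.node_id)
    return out


# -- stage: merging and enucleation --------------------------------------


def merge_identical(fns: Sequence[FunctionNode], dag: OntologyDAG) -> list[FunctionNode]:
    """Collapse FNs with identical protein sets into one node.

    The merged node keeps only the deepest (most specific) labels among
    all merged labels, ties all retained; its id concatenates the
    retained labels' ids with "+".
    """
    groups: dict[frozenset[str], list[FunctionNode]] = {}
    for fn in fns:
        groups.setdefault(frozenset(fn.proteins), []).append(fn)
    out: list[FunctionNode] = []
    for members, group in groups.items():
        if len(group) == 1:
            out.append(group[0])
            continue
        group.sort(key=lambda f: f.node_id)
        labels = sorted({t for fn in group for t in fn.labels})
        depths = {t: dag.depth(t) if t in dag else 0 for t in labels}
        dmax = max(depths.values())
        kept = frozenset(t for t in labels if depths[t] == dmax)
        node_id = "+".join(sorted(term_node_id(t) for t in kept))
        merged = FunctionNode(
            node_id=node_id,
            labels=kept,
            proteins=set(members),
            history=[("merged-from", tuple(f.node_id for f in group))],
        )
        # keep any agreeing PMS record for auditability
        for fn in group:
            for p, s in fn.pms.items():
                merged.pms.setdefault(p, s)
        out.append(merged)
    out.sort(key=lambda f: f.node_id)
    return out


def enucleate(fns: Sequence[FunctionNode]) -> list[FunctionNode]:
    """Subtract each FN's content from every FN it is a proper subset of.

    Runs to a fixpoint with a deterministic schedule (passes over FNs in
    descending protein-set size, then lexicographic node id).  FNs
    dropping under two proteins are discarded.
    """
    live = [fn.copy() for fn in fns]
    changed = True
    while changed:
        changed = False
        live.sort(key=lambda f: (-len(f.proteins), f.node_id))
        for host in live:
            for nucleus in live:
                if nucleus is host:
                    continue
                if nucleus.proteins < host.proteins:
                    host.proteins -= nucleus.proteins
                    host.history.append(("enucleated-by", nucleus.node_id))
                    changed = True
        survivors = []
        for fn in live:
            if len(fn.proteins) >= 2:
                survivors.append(fn)
            else:
                logger.info("FN %s discarded during enucleation (<2 proteins)", fn.node_id)
                changed = True
        live = survivors
    live.sort(key=lambda f: f.node_id)
    return live


def deduplicate(fns: Sequence[FunctionNode], dag: OntologyDAG) -> list[FunctionNode]:
    """Alternate merging and enucleation until neither changes anything
    (subtraction may create new identical protein sets)."""
    def signature(items: Sequence[FunctionNode]):
        return sorted((f.node_id, tuple(sorted(f.proteins))) for f in items)

    current = list(fns)
    while True:
        merged = merge_identical(current, dag)
        enucleated = enucleate(merged)
        if signature(enucleated) == signature(current):
            return enucleated
        current = enucleated


# -- stage: edges --------------------------------------------------------


def _internal_pairs(fns: Sequence[FunctionNode], net: PPINetwork) -> set[frozenset[str]]:
    """Interactions with both endpoints inside a single FN (internal PPI)."""
    internal: set[frozenset[str]] = set()
    for fn in fns:
        for v in fn.proteins:
            for w in net.neighbors(v) & fn.proteins:
                internal.add(frozenset((v, w)))
    return internal


def _crossing_counts(
    fn_a: FunctionNode,
    fn_b: FunctionNode,
    net: PPINetwork,
    internal: set[frozenset[str]] | None = None,
) -> tuple[int, int]:
    """(total, binary) crossing PPI between two FNs.

    A crossing PPI joins a protein exclusive to one FN with a protein
    exclusive to the other.  Internal PPI never count as crossing: an
    interaction whose endpoints lie together inside any single FN was
    already consumed in defining that FN, so it carries no evidence of
    a dependence between two other functions.
    """
    only_a = fn_a.proteins - fn_b.proteins
    only_b = fn_b.proteins - fn_a.proteins
    total = binary = 0
    for v in only_a:
        for w in net.neighbors(v) & only_b:
            if internal is not None and frozenset((v, w)) in internal:
                continue
            total += 1
            if BINARY in net.assay_classes(v, w):
                binary += 1
    return total, binary


def build_edges(
    fns: Sequence[FunctionNode], net: PPINetwork, cfg: PipelineConfig
) -> list[PGEdge]:
    """Link FN pairs sharing >1 protein or >1 qualifying crossing PPI.

    Under the default ``binary_only`` policy only crossings detected by a
    binary assay qualify; ``any_assay`` counts every crossing PPI (the
    literal pseudocode, which does not filter by assay).
    """
    edges: list[PGEdge] = []
    ordered = sorted(fns, key=lambda f: f.node_id)
    internal = _internal_pairs(ordered, net)
    for i, fa in enumerate(ordered):
        for fb in ordered[i + 1 :]:
            shared = len(fa.proteins & fb.proteins)
            total, binary = _crossing_counts(fa, fb, net, internal)
            qualifying = binary if cfg.edge_crossing_policy == "binary_only" else total
            if shared > 1 or qualifying > 1:
                edges.append(
                    PGEdge(
                        fa.node_id,
                        fb.node_id,
                        shared_protein_count=shared,
                        crossing_binary_ppi_count=binary,
                        crossing_total_ppi_count=total,
                    )
                )
    return edges


def baseline_edges(fns: Sequence[FunctionNode], net: PPINetwork) -> list[PGEdge]:
    """Comparison mode: link FNs on any single shared protein or any
    single crossing PPI of any assay class (strictly weaker criteria)."""
    edges: list[PGEdge] = []
    ordered = sorted(fns, key=lambda f: f.node_id)
    for i, fa in enumerate(ordered):
        for fb in ordered[i + 1 :]:
            shared = len(fa.proteins & fb.proteins)
            total, binary = _crossing_counts(fa, fb, net)
            if shared >= 1 or total >= 1:
                edges.append(
                    PGEdge(
                        fa.node_id,
                        fb.node_id,
                        shared_protein_count=shared,
                        crossing_binary_ppi_count=binary,
                        crossing_total_ppi_count=total,
                    )
                )
    return edges


# -- stage: NTS scoring and reduction ------------------------------------


def nts(fn: FunctionNode, clusters: ClusterSet, formula: str = JACCARD) -> float:
    """Node topological score: the FN's best overlap with any cluster."""
    best = 0.0
    fp = fn.proteins
    for cluster in clusters:
        a = len(fp & cluster.members)
        if formula == JACCARD:
            union = len(fp | cluster.members)
            score = 100.0 * a / union if union else 0.0
        elif formula == LITERAL:
            # denominator as printed: |FN∩C| + |FN∩C^c| + |FN^c∩C^c|
            b = len(fp - cluster.members)
            # d needs the universe; the printed formula is evaluated on
            # the union of all cluster members plus the FN
            d = len(_literal_universe(clusters, fp) - (fp | cluster.members))
            denom = a + b + d
            score = 100.0 * a / denom if denom else 0.0
        else:
            raise ValueError(f"unknown NTS formula {formula!r}")
        best = max(best, score)
    return best


def _literal_universe(clusters: ClusterSet, fn_proteins: set[str]) -> frozenset[str]:
    out = set(fn_proteins)
    for c in clusters:
        out |= c.members
    return frozenset(out)


def score_nts(
    fns: Sequence[FunctionNode], clusters: ClusterSet, formula: str = JACCARD
) -> None:
    for fn in fns:
        fn.nts = nts(fn, clusters, formula)


def reduce_by_nts(pg: ProcessGraph, threshold: float) -> ProcessGraph:
    """Drop nodes scoring below the NTS threshold, with incident edges."""
    kept = [n for n in pg.sorted_nodes() if (n.nts or 0.0) >= threshold]
    kept_ids = {n.node_id for n in kept}
    edges = [e for e in pg.sorted_edges() if e.u in kept_ids and e.v in kept_ids]
    out = ProcessGraph(kept, edges)
    logger.info(
        "NTS >= %g keeps %d/%d nodes, %d/%d edges",
        threshold, out.n_nodes, pg.n_nodes, out.n_edges, pg.n_edges,
    )
    return out


def nts_sweep(
    pg: ProcessGraph, thresholds: Iterable[float]
) -> list[tuple[float, int, int]]:
    """(threshold, surviving nodes, surviving edges) per threshold."""
    rows = []
    for t in thresholds:
        reduced = reduce_by_nts(pg, t)
        rows.append((t, reduced.n_nodes, reduced.n_edges))
    return rows


def select_by_core_fraction(
    pg: ProcessGraph,
    core: Iterable[str],
    rules: Sequence[tuple[float, float, float]],
) -> ProcessGraph:
    """Keep nodes satisfying at least one (nts_min, frac_min, frac_max)
    rule on NTS and the core-protein fraction of their content."""
    if not rules:
        return ProcessGraph(
            [n.copy() for n in pg.sorted_nodes()], list(pg.sorted_edges())
        )
    core = frozenset(core)
    kept = []
    for n in pg.sorted_nodes():
        frac = len(n.proteins & core) / len(n.proteins) if n.proteins else 0.0
        score = n.nts or 0.0
        for nts_min, f_min, f_max in rules:
            if score >= nts_min and f_min <= frac <= f_max:
                kept.append(n)
                break
    kept_ids = {n.node_id for n in kept}
    edges = [e for e in pg.sorted_edges() if e.u in kept_ids and e.v in kept_ids]
    return ProcessGraph(kept, edges)


# -- hypotheses ----------------------------------------------------------

#: the four candidate orientations of an open triple A-B-C
TRIPLE_ORIENTATIONS = (
    ("A->B", "B->C"),  # causal chain forward
    ("B->A", "C->B"),  # causal chain backward
    ("B->A", "B->C"),  # common cause B
    ("A->B", "C->B"),  # common effect B (collider)
)


def enumerate_triples(pg: ProcessGraph) -> list[dict]:
    """Open triples A-B-C (A-B and B-C linked, A-C not): each yields four
    candidate DAG orientations and a manipulate-B / assess-A,C design."""
    out = []
    for b in sorted(pg.nodes):
        nbrs = pg.neighbors(b)
        for i, a in enumerate(nbrs):
            for c in nbrs[i + 1 :]:
                if pg.has_edge(a, c):
                    continue
                out.append(
                    {
                        "a": a,
                        "b": b,
                        "c": c,
                        "orientations": [
                            tuple(
                                arrow.replace("A", a).replace("B", b).replace("C", c)
                                for arrow in pair
                            )
                            for pair in TRIPLE_ORIENTATIONS
                        ],
                        "design": f"manipulate {b}; assess {a} and {c}",
                    }
                )
    return out


# -- orchestration -------------------------------------------------------


@dataclass
class RunReport:
    """Counts after each pipeline stage, for audit and sweep reporting."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)  # (stage, nodes, edges)

    def record(self, stage: str, n_nodes: int, n_edges: int = 0) -> None:
        self.stages.append((stage, n_nodes, n_edges))

    def as_dict(self) -> dict:
        return {s: {"nodes": n, "edges": e} for s, n, e in self.stages}


def _core_fractions(fns: Sequence[FunctionNode], net: PPINetwork) -> None:
    core = net.core_proteins
    for fn in fns:
        fn.core_fraction = (
            len(fn.proteins & core) / len(fn.proteins) if fn.proteins else 0.0
        )


def run_pipeline(
    net: PPINetwork,
    dag: OntologyDAG,
    annotations: Mapping[str, Iterable[str]],
    cfg: PipelineConfig | None = None,
    clusters: ClusterSet | None = None,
) -> tuple[ProcessGraph, RunReport]:
    """Execute the full pipeline; deterministic given inputs and config."""
    cfg = cfg or PipelineConfig()
    report = RunReport()
    if net.n_proteins == 0:
        return ProcessGraph(), report

    known = filter_known_terms(annotations, dag)
    annmap = {p: dag.most_specific(ts) for p, ts in known.items()}
    report.record("most_specific_annotations", len(annmap))

    if clusters is None:
        clusters = build_cluster_set(net, cfg.k_min, cfg.k_max)

    fns = seed_function_nodes(net, annmap, dag, cfg.include_parent_seeding)
    if cfg.include_parent_seeding and cfg.parent_specificity_filter:
        all_labels = {t for fn in fns for t in fn.labels}
        keep = dag.most_specific(all_labels)
        fns = [fn for fn in fns if fn.labels & keep]
    report.record("seeded", len(fns))

    fns = refine_by_pms(fns, clusters, net.proteins, cfg)
    report.record("pms_refined", len(fns))

    fns = deduplicate(fns, dag)
    report.record("merged_enucleated", len(fns))

    edges = build_edges(fns, net, cfg)
    score_nts(fns, clusters, cfg.nts_formula)
    _core_fractions(fns, net)
    pg = ProcessGraph(fns, edges)
    report.record("edged_scored", pg.n_nodes, pg.n_edges)

    pg = reduce_by_nts(pg, cfg.nts_threshold)
    report.record("nts_reduced", pg.n_nodes, pg.n_edges)
    return pg, report


def run_baseline(
    net: PPINetwork,
    dag: OntologyDAG,
    annotations: Mapping[str, Iterable[str]],
    cfg: PipelineConfig | None = None,
) -> tuple[ProcessGraph, RunReport]:
    """Comparison pipeline without topological pruning.

    Seeds FNs and merges identical ones, then links any pair coupled by
    at least one shared protein or one crossing PPI of any assay class —
    the permissive linkage the method is designed to improve upon.
    """
    cfg = cfg or PipelineConfig()
    report = RunReport()
    if net.n_proteins == 0:
        return ProcessGraph(), report
    known = filter_known_terms(annotations, dag)
    annmap = {p: dag.most_specific(ts) for p, ts in known.items()}
    fns = seed_function_nodes(net, annmap, dag, cfg.include_parent_seeding)
    report.record("seeded", len(fns))
    fns = merge_identical(fns, dag)
    report.record("merged", len(fns))
    edges = baseline_edges(fns, net)
    clusters = build_cluster_set(net, cfg.k_min, cfg.k_max)
    score_nts(fns, clusters, cfg.nts_formula)
    _core_fractions(fns, net)
    pg = ProcessGraph(fns, edges)
    report.record("edged_scored", pg.n_nodes, pg.n_edges)
    return pg, report
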