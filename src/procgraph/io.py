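"""File formats: PPI tables, annotations, process-graph export, configs.

Input dialects: BioGRID tab3 or generic TSV for interactions, OBO for
the ontology (see :mod:`procgraph.ontology`), GAF 2.x or two-column TSV
for annotations.  Output: GraphML, SIF, DOT and a TSV node table, all
canonically ordered so identical graphs serialize byte-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import networkx as nx
import pandas as pd

from .process_graph import EdgeDirection, FunctionNode, PGEdge, ProcessGraph
from .synthetic import GroundTruth
from .topology import BINARY, CLUSTER, PPINetwork

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as in printed score tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# -- assay classification ------------------------------------------------

DEFAULT_BINARY_ASSAYS = (
    "Two-hybrid",
    "Biochemical Activity",
    "PCA",
)
DEFAULT_CLUSTER_ASSAYS = (
    "Affinity Capture-MS",
    "Affinity Capture-Western",
    "Co-crystal Structure",
    "Co-fractionation",
    "Co-localization",
    "Co-purification",
    "Far Western",
    "Reconstituted Complex",
)


@dataclass
class AssayClassTable:
    """Maps assay names to the binary / cluster class.

    Binary assays (e.g. two-hybrid) report bona fide direct contacts;
    cluster assays (e.g. affinity capture) report co-membership in a
    complex.  ``unknown_policy`` decides how unlisted assay names are
    handled: ``warn_cluster`` (default, conservative), ``warn_binary``
    or ``error``.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    unknown_policy: str = "warn_cluster"

    def __post_init__(self):
        if self.unknown_policy not in ("warn_cluster", "warn_binary", "error"):
            raise ValueError(f"bad unknown_policy {self.unknown_policy!r}")
        self.mapping = {k.strip().lower(): v for k, v in self.mapping.items()}
        bad = set(self.mapping.values()) - {BINARY, CLUSTER}
        if bad:
            raise ValueError(f"assay classes must be binary/cluster, got {bad}")

    @classmethod
    def default(cls, unknown_policy: str = "warn_cluster") -> "AssayClassTable":
        mapping = {name: BINARY for name in DEFAULT_BINARY_ASSAYS}
        mapping.update({name: CLUSTER for name in DEFAULT_CLUSTER_ASSAYS})
        return cls(mapping, unknown_policy)

    def classify(self, assay_name: str) -> str:
        key = assay_name.strip().lower()
        cls_ = self.mapping.get(key)
        if cls_ is not None:
            return cls_
        if self.unknown_policy == "error":
            raise FormatError(f"unknown assay name {assay_name!r}")
        fallback = CLUSTER if self.unknown_policy == "warn_cluster" else BINARY
        logger.warning("unknown assay %r classified as %s", assay_name, fallback)
        return fallback


# -- PPI reading ---------------------------------------------------------

_A_COLUMNS = (
    "interactor a",
    "interactor_a",
    "systematic name interactor a",
    "official symbol interactor a",
    "a",
)
_B_COLUMNS = (
    "interactor b",
    "interactor_b",
    "systematic name interactor b",
    "official symbol interactor b",
    "b",
)
_ASSAY_COLUMNS = ("experimental system", "experimental_system", "assay", "system")
_TYPE_COLUMNS = ("experimental system type", "experimental_system_type", "system_type")


def _pick(columns: dict[str, str], candidates: tuple[str, ...]) -> str | None:
    for cand in candidates:
        if cand in columns:
            return columns[cand]
    return None


def read_core_list(path) -> frozenset[str]:
    """One protein id per line; '#' comments and blanks ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return frozenset(out)


def read_ppi(
    path,
    assay_table: AssayClassTable | None = None,
    core_list: frozenset[str] | None = None,
) -> PPINetwork:
    """Read a PPI edge table (generic TSV or BioGRID tab3 dialect).

    Requires interactor A/B columns; an experimental-system column
    supplies assay names.  When a system-type column is present only
    ``physical`` rows are kept.  Self-loops are dropped and duplicate
    records merged (both logged and counted on the returned network's
    ``ingest_stats``).  Absent ``core_list`` marks every protein core.
    """
    assay_table = assay_table or AssayClassTable.default()
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    columns = {c.strip().lower().lstrip("#"): c for c in df.columns}
    col_a = _pick(columns, _A_COLUMNS)
    col_b = _pick(columns, _B_COLUMNS)
    if col_a is None:
        raise FormatError("no interactor A column found (expected e.g. 'Interactor A')")
    if col_b is None:
        raise FormatError("no interactor B column found (expected e.g. 'Interactor B')")
    col_assay = _pick(columns, _ASSAY_COLUMNS)
    col_type = _pick(columns, _TYPE_COLUMNS)

    n_rows = len(df)
    n_non_physical = 0
    if col_type is not None:
        physical = df[col_type].str.strip().str.lower() == "physical"
        n_non_physical = int((~physical).sum())
        df = df[physical]

    net = PPINetwork()
    for _, row in df.iterrows():
        a, b = str(row[col_a]).strip(), str(row[col_b]).strip()
        if col_assay is not None and pd.notna(row[col_assay]):
            assay = str(row[col_assay]).strip()
            net.add_interaction(a, b, {assay}, {assay_table.classify(assay)})
        else:
            net.add_interaction(a, b)
    if core_list is not None:
        net.set_core(core_list)
    net.ingest_stats = {
        "rows": n_rows,
        "non_physical_skipped": n_non_physical,
        "self_loops_dropped": net.n_self_loops_dropped,
        "duplicates_merged": net.n_duplicates_merged,
        "interactions_kept": net.n_interactions,
    }
    assert (
        n_rows
        == n_non_physical
        + net.n_self_loops_dropped
        + net.n_duplicates_merged
        + net.n_interactions
    )
    logger.info("read %d rows -> %s", n_rows, net.ingest_stats)
    return net


def write_ppi_tsv(net: PPINetwork, path) -> None:
    rows = []
    for a, b, assays, _classes in net.interactions():
        u, v = sorted((a, b))
        for assay in sorted(assays) or [""]:
            rows.append((u, v, assay))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("Interactor A\tInteractor B\tExperimental System\n")
        for u, v, assay in rows:
            fh.write(f"{u}\t{v}\t{assay}\n")


# -- annotation reading --------------------------------------------------


def read_annotations(
    path, dag, aspect: str | None = None
) -> dict[str, frozenset[str]]:
    """Read GAF 2.x or two-column TSV protein-to-term annotations.

    GAF rows are keyed by DB Object Symbol (column 3) and filtered by
    aspect (column 9) when requested; the aspect filter does not apply
    to the TSV dialect.  Terms absent from the ontology are dropped with
    a warning; malformed lines are skipped (a hard error above 10%).
    """
    lines = Path(path).read_text().splitlines()
    is_gaf = any(line.startswith("!gaf-version") for line in lines[:5]) or any(
        len(line.split("\t")) >= 15 for line in lines[:20] if line and not line.startswith("!")
    )
    raw: dict[str, set[str]] = {}
    n_data = n_malformed = n_unknown_term = 0
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("!") or line.startswith("#"):
            continue
        fields = line.split("\t")
        n_data += 1
        if is_gaf:
            if len(fields) < 15:
                n_malformed += 1
                logger.warning("%s:%d: malformed GAF line skipped", path, lineno)
                continue
            protein, term, row_aspect = fields[2], fields[4], fields[8]
            if aspect is not None and row_aspect != aspect:
                continue
        else:
            if len(fields) < 2 or not fields[0] or not fields[1]:
                n_malformed += 1
                logger.warning("%s:%d: malformed TSV line skipped", path, lineno)
                continue
            protein, term = fields[0].strip(), fields[1].strip()
        if term not in dag:
            n_unknown_term += 1
            logger.warning("%s:%d: term %s absent from ontology, dropped", path, lineno, term)
            continue
        raw.setdefault(protein, set()).add(term)
    if n_data and n_malformed / n_data > 0.10:
        raise FormatError(
            f"{path}: {n_malformed}/{n_data} malformed lines (>10%), refusing input"
        )
    return {p: frozenset(ts) for p, ts in raw.items()}


def write_annotations_tsv(annotations: dict[str, frozenset[str]], path) -> None:
    with open(path, "w") as fh:
        for protein in sorted(annotations):
            for term in sorted(annotations[protein]):
                fh.write(f"{protein}\t{term}\n")


def write_obo(dag, path) -> None:
    """Minimal OBO 1.2 writer (id, name, is_a), canonical term order."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: procgraph-synthetic\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {dag.name(term)}\n")
            for parent in sorted(dag.parents(term)):
                fh.write(f"is_a: {parent} ! {dag.name(parent)}\n")


def write_truth_tsv(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("record\tfield1\tfield2\n")
        for term in sorted(truth.module_map):
            fh.write(f"module\t{term}\t{'|'.join(sorted(truth.module_map[term]))}\n")
        for pair in sorted(tuple(sorted(p)) for p in truth.chain_edges):
            fh.write(f"chain_edge\t{pair[0]}\t{pair[1]}\n")
        for pair in sorted(tuple(sorted(p)) for p in truth.forbidden_edges):
            fh.write(f"forbidden_edge\t{pair[0]}\t{pair[1]}\n")


def read_truth_tsv(path) -> GroundTruth:
    module_map: dict[str, frozenset[str]] = {}
    chain: set[frozenset[str]] = set()
    forbidden: set[frozenset[str]] = set()
    for line in Path(path).read_text().splitlines()[1:]:
        kind, f1, f2 = line.rstrip("\n").split("\t")
        if kind == "module":
            module_map[f1] = frozenset(f2.split("|"))
        elif kind == "chain_edge":
            chain.add(frozenset((f1, f2)))
        elif kind == "forbidden_edge":
            forbidden.add(frozenset((f1, f2)))
    return GroundTruth(module_map, chain, forbidden)


# -- process-graph export ------------------------------------------------

PG_FORMATS = ("graphml", "sif", "dot", "tsv")


def _pg_to_nx(pg: ProcessGraph) -> nx.Graph:
    g = nx.Graph()
    for node in pg.sorted_nodes():
        attrs = {
            "labels": "|".join(sorted(node.labels)),
            "proteins": "|".join(sorted(node.proteins)),
        }
        if node.nts is not None:
            attrs["nts"] = float(node.nts)
        if node.core_fraction is not None:
            attrs["core_fraction"] = float(node.core_fraction)
        g.add_node(node.node_id, **attrs)
    for edge in pg.sorted_edges():
        attrs = {
            "shared_protein_count": edge.shared_protein_count,
            "crossing_binary_ppi_count": edge.crossing_binary_ppi_count,
            "crossing_total_ppi_count": edge.crossing_total_ppi_count,
        }
        if edge.direction is not None:
            attrs["direction_from"] = edge.direction.from_id
            attrs["direction_to"] = edge.direction.to_id
            attrs["direction_rule"] = edge.direction.rule
            attrs["direction_note"] = edge.direction.note
        g.add_edge(edge.u, edge.v, **attrs)
    return g


def write_pg(pg: ProcessGraph, path, format: str = "graphml") -> None:
    """Write a process graph in the given format with canonical ordering."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml_xml(_pg_to_nx(pg), path)
    elif format == "sif":
        with open(path, "w") as fh:
            for edge in pg.sorted_edges():
                fh.write(f"{edge.u}\tfn-fn\t{edge.v}\n")
            linked = {n for e in pg.edges for n in e}
            for node_id in sorted(set(pg.nodes) - linked):
                fh.write(f"{node_id}\n")
    elif format == "dot":
        with open(path, "w") as fh:
            fh.write("graph process_graph {\n")
            for node in pg.sorted_nodes():
                label = "+".join(sorted(node.labels))
                nts_txt = "" if node.nts is None else f"\\nNTS {round_half_up(node.nts)}"
                fh.write(f'  "{node.node_id}" [label="{label}{nts_txt}"];\n')
            for edge in pg.sorted_edges():
                fh.write(f'  "{edge.u}" -- "{edge.v}";\n')
            fh.write("}\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("node_id\tlabels\tn_proteins\tproteins\tnts\tcore_fraction\n")
            for node in pg.sorted_nodes():
                nts_txt = "" if node.nts is None else f"{round_half_up(node.nts)}"
                cf_txt = (
                    "" if node.core_fraction is None else f"{round(node.core_fraction, 4)}"
                )
                fh.write(
                    f"{node.node_id}\t{'|'.join(sorted(node.labels))}\t"
                    f"{len(node.proteins)}\t{'|'.join(sorted(node.proteins))}\t"
                    f"{nts_txt}\t{cf_txt}\n"
                )
    else:
        raise ValueError(f"unknown process-graph format {format!r}; use one of {PG_FORMATS}")


def read_pg(path) -> ProcessGraph:
    """Read a GraphML process graph written by :func:`write_pg`."""
    g = nx.read_graphml(path)
    nodes = []
    for node_id in sorted(g.nodes):
        data = g.nodes[node_id]
        nodes.append(
            FunctionNode(
                node_id=str(node_id),
                labels=frozenset(data.get("labels", "").split("|")) - {""},
                proteins=set(data.get("proteins", "").split("|")) - {""},
                nts=float(data["nts"]) if "nts" in data else None,
                core_fraction=(
                    float(data["core_fraction"]) if "core_fraction" in data else None
                ),
            )
        )
    edges = []
    for u, v in sorted((min(str(u), str(v)), max(str(u), str(v))) for u, v in g.edges):
        data = g.edges[u, v]
        direction = None
        if "direction_from" in data:
            direction = EdgeDirection(
                data["direction_from"],
                data["direction_to"],
                int(data["direction_rule"]),
                data.get("direction_note", ""),
            )
        edges.append(
            PGEdge(
                u,
                v,
                shared_protein_count=int(data.get("shared_protein_count", 0)),
                crossing_binary_ppi_count=int(data.get("crossing_binary_ppi_count", 0)),
                crossing_total_ppi_count=int(data.get("crossing_total_ppi_count", 0)),
                direction=direction,
            )
        )
    return ProcessGraph(nodes, edges)


# -- user-supplied edge directions ---------------------------------------


def read_directions(path) -> list[EdgeDirection]:
    """TSV of user-supplied edge orientations: from, to, rule (1-6), note."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if lineno == 1 and fields[0].lower() in ("from", "from_id"):
            continue
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected from/to/rule columns")
        note = fields[3] if len(fields) > 3 else ""
        out.append(EdgeDirection(fields[0], fields[1], int(fields[2]), note))
    return out


def apply_directions(pg: ProcessGraph, directions) -> int:
    """Attach user-supplied orientations to matching edges; returns count."""
    applied = 0
    for d in directions:
        key = (min(d.from_id, d.to_id), max(d.from_id, d.to_id))
        edge = pg.edges.get(key)
        if edge is None:
            logger.warning("direction for absent edge %s-%s ignored", d.from_id, d.to_id)
            continue
        edge.direction = d
        applied += 1
    return applied
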