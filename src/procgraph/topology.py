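"""PPI graph container, k-clique / clique-percolation clusters, summaries.

The interaction network is a simple undirected graph: one edge per
protein pair, carrying the set of detecting assays and their derived
classes (``binary`` contact assays vs ``cluster`` co-complex assays).
The topological side of the method rests on the cluster set C: all
fully inter-connected k-protein subgraphs (k-cliques) together with
their percolation communities (unions of k-cliques chained through
shared (k-1)-node overlaps).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import networkx as nx
from networkx.algorithms.community import k_clique_communities as _nx_kcc

logger = logging.getLogger(__name__)

BINARY = "binary"
CLUSTER = "cluster"


class PPINetwork:
    """Simple undirected protein-protein interaction graph.

    Nodes carry an ``is_core`` flag (member of the seed/domain protein
    set vs first-degree neighbor); edges carry the merged ``assays`` name
    set and the derived ``assay_class`` flag set.
    """

    def __init__(self):
        self.g = nx.Graph()
        self.n_self_loops_dropped = 0
        self.n_duplicates_merged = 0

    # -- construction ---------------------------------------------------

    def add_protein(self, protein_id: str, is_core: bool = True) -> None:
        if protein_id in self.g:
            # core status widens only explicitly; keep existing flag
            return
        self.g.add_node(protein_id, is_core=bool(is_core))

    def set_core(self, core: Iterable[str]) -> None:
        """Mark exactly the given proteins as core, everything else neighbor."""
        core = set(core)
        for n in self.g.nodes:
            self.g.nodes[n]["is_core"] = n in core

    def add_interaction(
        self,
        a: str,
        b: str,
        assays: Iterable[str] = (),
        assay_classes: Iterable[str] = (),
    ) -> bool:
        """Add or merge one interaction record; returns False for self-loops."""
        if a == b:
            self.n_self_loops_dropped += 1
            logger.warning("dropping self-interaction %s-%s", a, b)
            return False
        for p in (a, b):
            if p not in self.g:
                self.g.add_node(p, is_core=True)
        assays = set(assays)
        classes = set(assay_classes)
        if classes - {BINARY, CLUSTER}:
            raise ValueError(f"unknown assay class in {classes}")
        if self.g.has_edge(a, b):
            self.n_duplicates_merged += 1
            self.g.edges[a, b]["assays"] |= assays
            self.g.edges[a, b]["assay_class"] |= classes
        else:
            self.g.add_edge(a, b, assays=assays, assay_class=classes)
        return True

    # -- queries ---------------------------------------------------------

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self.g.nodes)

    @property
    def n_proteins(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_interactions(self) -> int:
        return self.g.number_of_edges()

    def is_core(self, protein_id: str) -> bool:
        return bool(self.g.nodes[protein_id]["is_core"])

    @property
    def core_proteins(self) -> frozenset[str]:
        return frozenset(n for n, d in self.g.nodes(data=True) if d["is_core"])

    def has_interaction(self, a: str, b: str) -> bool:
        return self.g.has_edge(a, b)

    def assay_classes(self, a: str, b: str) -> frozenset[str]:
        return frozenset(self.g.edges[a, b]["assay_class"])

    def neighbors(self, protein_id: str) -> frozenset[str]:
        return frozenset(self.g.neighbors(protein_id))

    def interactions(self) -> Iterator[tuple[str, str, set[str], set[str]]]:
        for a, b, d in self.g.edges(data=True):
            yield a, b, d["assays"], d["assay_class"]


# -- clusters ------------------------------------------------------------


@dataclass(frozen=True)
class ProteinCluster:
    """A topological pattern: a k-clique or a k-clique community."""

    kind: str  # "clique" | "community"
    k: int
    members: frozenset[str]

    def __post_init__(self):
        if self.kind not in ("clique", "community"):
            raise ValueError(f"cluster kind must be clique/community, got {self.kind!r}")


class ClusterSet:
    """Deduplicated collection of clusters with a protein membership index."""

    def __init__(self, clusters: Iterable[ProteinCluster] = ()):
        self._clusters: list[ProteinCluster] = []
        self._seen: set[tuple[str, int, frozenset[str]]] = set()
        self._index: dict[str, list[ProteinCluster]] = {}
        for c in clusters:
            self.add(c)

    def add(self, cluster: ProteinCluster) -> None:
        key = (cluster.kind, cluster.k, cluster.members)
        if key in self._seen:
            return
        self._seen.add(key)
        self._clusters.append(cluster)
        for p in cluster.members:
            self._index.setdefault(p, []).append(cluster)

    def __len__(self) -> int:
        return len(self._clusters)

    def __iter__(self) -> Iterator[ProteinCluster]:
        return iter(self._clusters)

    def containing(self, protein_id: str) -> list[ProteinCluster]:
        """Clusters having the protein as a member (empty list if none)."""
        return self._index.get(protein_id, [])


def find_k_cliques(net: PPINetwork, k: int) -> set[ProteinCluster]:
    """All complete k-vertex subgraphs, maximal or not, each once."""
    if k < 3:
        raise ValueError(f"clique order k must be >= 3, got {k}")
    out = set()
    for clique in nx.enumerate_all_cliques(net.g):
        if len(clique) == k:
            out.add(ProteinCluster("clique", k, frozenset(clique)))
    return out


def k_clique_communities(net: PPINetwork, k: int) -> set[ProteinCluster]:
    """Clique-percolation communities: unions of k-cliques chained by
    (k-1)-node overlaps, each community reported as its member union."""
    if k < 3:
        raise ValueError(f"clique order k must be >= 3, got {k}")
    return {
        ProteinCluster("community", k, frozenset(c)) for c in _nx_kcc(net.g, k)
    }


def max_clique_order(net: PPINetwork) -> int:
    """Largest k for which the graph contains a k-clique (0 if empty)."""
    if net.n_proteins == 0:
        return 0
    return max(len(c) for c in nx.find_cliques(net.g))


def build_cluster_set(
    net: PPINetwork, k_min: int = 3, k_max: int | str = "auto"
) -> ClusterSet:
    """Union of k-cliques and k-clique communities for k in [k_min, k_max].

    ``k_max="auto"`` sweeps up to the largest clique order present.
    """
    if k_min < 3:
        raise ValueError(f"k_min must be >= 3, got {k_min}")
    if k_max == "auto":
        k_max_val = max_clique_order(net)
    else:
        k_max_val = int(k_max)
        if k_max_val < k_min:
            raise ValueError(f"k_max {k_max_val} < k_min {k_min}")
    clusters = ClusterSet()
    if net.n_proteins == 0:
        return clusters
    # one pass over all cliques, grouped by order
    by_k: dict[int, list[frozenset[str]]] = {}
    for clique in nx.enumerate_all_cliques(net.g):
        if k_min <= len(clique) <= k_max_val:
            by_k.setdefault(len(clique), []).append(frozenset(clique))
    for k in range(k_min, k_max_val + 1):
        for members in by_k.get(k, []):
            clusters.add(ProteinCluster("clique", k, members))
        for comm in _nx_kcc(net.g, k):
            clusters.add(ProteinCluster("community", k, frozenset(comm)))
    logger.info(
        "cluster set: %d clusters (k in [%d, %d])", len(clusters), k_min, k_max_val
    )
    return clusters


# -- descriptive statistics ----------------------------------------------


def mean_degree(n_nodes: int, n_edges: int) -> float:
    """Average connectivity 2m/n of a simple graph given its counts."""
    if n_nodes == 0:
        return math.nan
    return 2.0 * n_edges / n_nodes


def network_summary(net: PPINetwork) -> dict:
    """Node/edge counts, mean degree, mean clustering, path length.

    Mean clustering counts degree<2 nodes as 0.  On a disconnected graph
    the characteristic path length is computed on the largest connected
    component (logged).  An empty graph reports NaN statistics.
    """
    n, m = net.n_proteins, net.n_interactions
    if n == 0:
        return {
            "n_proteins": 0,
            "n_interactions": 0,
            "mean_degree": math.nan,
            "mean_clustering": math.nan,
            "char_path_length": math.nan,
        }
    g = net.g
    summary = {
        "n_proteins": n,
        "n_interactions": m,
        "mean_degree": mean_degree(n, m),
        "mean_clustering": nx.average_clustering(g),
    }
    if nx.is_connected(g):
        component = g
    else:
        component = g.subgraph(max(nx.connected_components(g), key=len))
        logger.info(
            "graph disconnected; path length computed on largest component "
            "(%d of %d proteins)",
            component.number_of_nodes(),
            n,
        )
    if component.number_of_nodes() > 1:
        summary["char_path_length"] = nx.average_shortest_path_length(component)
    else:
        summary["char_path_length"] = math.nan
    return summary


def _pairwise_adjacent(net: PPINetwork, members: Iterable[str]) -> bool:
    ms = list(members)
    return all(net.g.has_edge(a, b) for a, b in itertools.combinations(ms, 2))
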