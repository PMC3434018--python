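"""Annotation hierarchies (GO-like DAGs) and most-specific-term filtering.

A functional vocabulary such as the Gene Ontology is a directed acyclic
graph of terms: each term may have one or more parents reached through
``is_a`` / ``part_of`` links, and every non-root term has a directed path
up to a root.  Proteins are annotated not only with the specific term that
defines a function but also, implicitly, with every ancestor of that term;
before functions are mapped onto an interaction network the annotation set
of each protein is therefore reduced to its most specific terms (no
retained term may be an ancestor of another annotated term).

Term *depth* is used as the specificity measure when merged function nodes
must choose among competing labels: by default it is the length of the
longest directed path from the term up to a root (the conventional
GO reading of "distance from the root"), with a shortest-path variant
available.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: hierarchical OBO relations honoured by default
DEFAULT_RELATIONS = ("is_a", "part_of")


class UnknownTermError(KeyError):
    """Raised when an operation references a term absent from the ontology."""

    def __init__(self, term_id: str):
        super().__init__(term_id)
        self.term_id = term_id

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"unknown ontology term: {self.term_id!r}"


class OntologyDAG:
    """A rooted, acyclic hierarchy of named terms.

    Parameters
    ----------
    terms:
        Mapping of term id to human-readable name.
    parent_links:
        Mapping of child term id to the ids of its direct parents.  Every
        id appearing as a parent must also be a key of ``terms``.
    depth_mode:
        ``"longest"`` (default) measures term depth as the longest
        directed path to any root; ``"shortest"`` as the shortest path to
        the nearest root.
    """

    def __init__(
        self,
        terms: Mapping[str, str],
        parent_links: Mapping[str, Iterable[str]] | None = None,
        depth_mode: str = "longest",
    ):
        if depth_mode not in ("longest", "shortest"):
            raise ValueError(f"depth_mode must be 'longest' or 'shortest', got {depth_mode!r}")
        self._names: dict[str, str] = dict(terms)
        if not all(self._names):
            raise ValueError("term ids must be non-empty strings")
        self._parents: dict[str, frozenset[str]] = {t: frozenset() for t in self._names}
        for child, parents in (parent_links or {}).items():
            if child not in self._names:
                raise UnknownTermError(child)
            ps = frozenset(parents)
            for p in ps:
                if p not in self._names:
                    raise UnknownTermError(p)
            self._parents[child] = ps
        self.depth_mode = depth_mode
        self._check_acyclic()
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._depth_cache: dict[str, int] = {}

    # -- construction ---------------------------------------------------

    @classmethod
    def from_obo(
        cls,
        path,
        relations: Iterable[str] = DEFAULT_RELATIONS,
        namespace: str | None = None,
        depth_mode: str = "longest",
    ) -> "OntologyDAG":
        """Read an OBO 1.2/1.4 file (``[Term]`` stanzas only).

        Obsolete terms are skipped.  ``relations`` selects which edge
        types form the hierarchy (``is_a`` and ``part_of`` by default);
        ``namespace`` optionally restricts terms to one OBO namespace
        (e.g. ``biological_process``).
        """
        graph = obonet.read_obo(path, ignore_obsolete=True)
        relations = set(relations)
        terms: dict[str, str] = {}
        for node, data in graph.nodes(data=True):
            if namespace is not None and data.get("namespace") != namespace:
                continue
            terms[node] = data.get("name", node)
        links: dict[str, set[str]] = {t: set() for t in terms}
        for child, parent, rel in graph.edges(keys=True):
            if rel in relations and child in terms and parent in terms:
                links[child].add(parent)
        logger.info("loaded %d terms from %s", len(terms), path)
        return cls(terms, links, depth_mode=depth_mode)

    # -- basic queries ---------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._names

    def __len__(self) -> int:
        return len(self._names)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._names)

    def name(self, term_id: str) -> str:
        self._require(term_id)
        return self._names[term_id]

    @property
    def roots(self) -> frozenset[str]:
        """Terms with no parents."""
        return frozenset(t for t, ps in self._parents.items() if not ps)

    def parents(self, term_id: str) -> frozenset[str]:
        """Direct parents of a term (empty for roots)."""
        self._require(term_id)
        return self._parents[term_id]

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Transitive closure of :meth:`parents`; the term itself excluded."""
        self._require(term_id)
        return self._ancestors(term_id)

    def _ancestors(self, term_id: str) -> frozenset[str]:
        cached = self._anc_cache.get(term_id)
        if cached is None:
            out: set[str] = set()
            for p in self._parents[term_id]:
                out.add(p)
                out |= self._ancestors(p)
            cached = frozenset(out)
            self._anc_cache[term_id] = cached
        return cached

    def depth(self, term_id: str) -> int:
        """Directed-path distance from the term up to a root.

        Longest path under ``depth_mode="longest"`` (default), shortest
        under ``"shortest"``.  Roots have depth 0.
        """
        self._require(term_id)
        return self._depth(term_id)

    def _depth(self, term_id: str) -> int:
        cached = self._depth_cache.get(term_id)
        if cached is None:
            ps = self._parents[term_id]
            if not ps:
                cached = 0
            else:
                agg = max if self.depth_mode == "longest" else min
                cached = agg(self._depth(p) + 1 for p in ps)
            self._depth_cache[term_id] = cached
        return cached

    # -- specificity filtering -------------------------------------------

    def most_specific(self, term_ids: Iterable[str]) -> frozenset[str]:
        """Reduce a term set to its most specific members.

        A term is retained iff it is an ancestor of no other term in the
        input: the surviving set contains no hierarchically ordered pair.
        Idempotent.
        """
        ts = set(term_ids)
        for t in ts:
            self._require(t)
        dropped = {a for b in ts for a in self._ancestors(b) if a in ts}
        return frozenset(ts - dropped)

    # -- internals -------------------------------------------------------

    def _require(self, term_id: str) -> None:
        if term_id not in self._names:
            raise UnknownTermError(term_id)

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._names)
        for child, ps in self._parents.items():
            g.add_edges_from((child, p) for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")


def filter_known_terms(
    annotations: Mapping[str, Iterable[str]], dag: OntologyDAG
) -> dict[str, frozenset[str]]:
    """Drop annotated terms absent from the ontology, with a logged warning."""
    out: dict[str, frozenset[str]] = {}
    n_dropped = 0
    for protein, terms in annotations.items():
        known = frozenset(t for t in terms if t in dag)
        n_dropped += len(set(terms)) - len(known)
        if known:
            out[protein] = known
    if n_dropped:
        logger.warning("dropped %d annotation(s) to terms absent from the ontology", n_dropped)
    return out
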