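"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools
import random

import networkx as nx
import pytest

from procgraph.ontology import OntologyDAG
from procgraph.topology import PPINetwork, BINARY, CLUSTER


# -- small deterministic ontologies --------------------------------------


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """a <- b <- c (c is the most specific term)."""
    return OntologyDAG({"a": "a", "b": "b", "c": "c"}, {"b": {"a"}, "c": {"b"}})


@pytest.fixture
def diamond_dag() -> OntologyDAG:
    """a <- b, a <- c, b <- d, c <- d."""
    return OntologyDAG(
        {"a": "a", "b": "b", "c": "c", "d": "d"},
        {"b": {"a"}, "c": {"a"}, "d": {"b", "c"}},
    )


def random_dag(rng: random.Random, n_terms: int) -> OntologyDAG:
    """Random DAG: each term may take parents among earlier terms."""
    names = [f"t{i}" for i in range(n_terms)]
    links = {}
    for i in range(1, n_terms):
        k = rng.randint(0, min(2, i))
        if k:
            links[names[i]] = set(rng.sample(names[:i], k))
    return OntologyDAG({t: t for t in names}, links)


# -- ontology oracles -----------------------------------------------------


def enumerate_root_paths(dag: OntologyDAG, term: str) -> list[list[str]]:
    """All directed paths from a term up to a root, by exhaustive DFS."""
    parents = dag.parents(term)
    if not parents:
        return [[term]]
    out = []
    for p in sorted(parents):
        for path in enumerate_root_paths(dag, p):
            out.append([term] + path)
    return out


def oracle_ancestors(dag: OntologyDAG, term: str) -> set[str]:
    return {t for path in enumerate_root_paths(dag, term) for t in path} - {term}


def oracle_depth(dag: OntologyDAG, term: str) -> int:
    return max(len(path) - 1 for path in enumerate_root_paths(dag, term))


# -- graphs ---------------------------------------------------------------


def net_from_edges(edges, binary=True) -> PPINetwork:
    net = PPINetwork()
    cls = {BINARY} if binary else {CLUSTER}
    assay = {"Two-hybrid"} if binary else {"Affinity Capture-MS"}
    for a, b in edges:
        net.add_interaction(str(a), str(b), assay, cls)
    return net


def random_net(rng: random.Random, n: int, p: float) -> PPINetwork:
    g = nx.gnp_random_graph(n, p, seed=rng.randint(0, 2**31 - 1))
    net = PPINetwork()
    for i in g.nodes:
        net.add_protein(str(i))
    for a, b in g.edges:
        binary = rng.random() < 0.5
        net.add_interaction(
            str(a),
            str(b),
            {"Two-hybrid"} if binary else {"Affinity Capture-MS"},
            {BINARY} if binary else {CLUSTER},
        )
    return net


# -- clique / community oracles -------------------------------------------


def oracle_k_cliques(net: PPINetwork, k: int) -> set[frozenset[str]]:
    """Exhaustive subset enumeration: every k-subset that is complete."""
    nodes = sorted(net.proteins)
    out = set()
    for subset in itertools.combinations(nodes, k):
        if all(net.has_interaction(a, b) for a, b in itertools.combinations(subset, 2)):
            out.add(frozenset(subset))
    return out


def oracle_k_clique_communities(net: PPINetwork, k: int) -> set[frozenset[str]]:
    """Percolation by hand: union-find over k-cliques sharing k-1 nodes."""
    cliques = sorted(oracle_k_cliques(net, k), key=sorted)
    parent = list(range(len(cliques)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(cliques)), 2):
        if len(cliques[i] & cliques[j]) == k - 1:
            parent[find(i)] = find(j)
    groups: dict[int, set[str]] = {}
    for i, cl in enumerate(cliques):
        groups.setdefault(find(i), set()).update(cl)
    return {frozenset(g) for g in groups.values()}


# -- PMS / NTS oracles -----------------------------------------------------


def oracle_two_by_two(fn: set[str], cluster: set[str], universe: set[str]):
    """Tally the 2x2 membership table one element at a time."""
    a = b = c = d = 0
    for p in universe:
        in_fn, in_c = p in fn, p in cluster
        if in_fn and in_c:
            a += 1
        elif in_fn:
            b += 1
        elif in_c:
            c += 1
        else:
            d += 1
    return a, b, c, d
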