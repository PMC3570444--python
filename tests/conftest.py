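"""Shared fixtures and independent oracles.

The oracles here deliberately use different algorithms from the package:
d-separation via networkx's reachability-based ``is_d_separator`` (the
package enumerates paths and applies blocking rules), and sufficiency via
the adjustment criterion on the proper-backdoor graph (the package checks
open noncausal paths).  Agreement between the two routes is what the
identification tests assert.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from dagcie.dag_core import Dag, Node, Query
from dagcie.identification import candidate_pool
from dagcie.synthetic_data import fixture, simulate


# ---------------------------------------------------------------------------
# random DAGs


def random_dag(rng: np.random.Generator, max_nodes: int = 8, edge_p: float = 0.35) -> Dag:
    n = int(rng.integers(3, max_nodes + 1))
    names = [f"V{i}" for i in range(n)]
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < edge_p
    ]
    return Dag([Node(x) for x in names], edges)


def mid_query(dag: Dag) -> Query:
    """Exposure in the middle of the topological order, outcome at the end,
    so confounding structures actually occur."""
    names = list(dag.node_names)
    return Query(names[len(names) // 2], names[-1])


# ---------------------------------------------------------------------------
# independent oracles


def oracle_d_separated(dag: Dag, x: str, y: str, given) -> bool:
    g = nx.DiGraph()
    g.add_nodes_from(dag.node_names)
    g.add_edges_from(dag.edges)
    return nx.is_d_separator(g, {x}, {y}, set(given) | set(dag.selection_nodes()))


def proper_backdoor_graph(dag: Dag, query: Query) -> nx.DiGraph:
    """Remove the first edge of every proper causal path."""
    g = nx.DiGraph()
    g.add_nodes_from(dag.node_names)
    g.add_edges_from(dag.edges)
    for child in list(g.successors(query.exposure)):
        if child == query.outcome or query.outcome in nx.descendants(g, child):
            g.remove_edge(query.exposure, child)
    return g


def oracle_is_sufficient(dag: Dag, query: Query, s) -> bool:
    pbd = proper_backdoor_graph(dag, query)
    return nx.is_d_separator(
        pbd, {query.exposure}, {query.outcome}, set(s) | set(dag.selection_nodes())
    )


def oracle_minimal_sufficient_sets(dag: Dag, query: Query) -> list[frozenset[str]]:
    pool = candidate_pool(dag, query)
    sufficient: list[frozenset[str]] = []
    for size in range(len(pool) + 1):
        for combo in itertools.combinations(pool, size):
            s = frozenset(combo)
            if any(m <= s for m in sufficient):
                continue
            if oracle_is_sufficient(dag, query, s):
                sufficient.append(s)
    return sorted(sufficient, key=lambda s: (len(s), tuple(sorted(s))))


# ---------------------------------------------------------------------------
# datasets (session-scoped: simulated once per test run)


@pytest.fixture(scope="session")
def fig1():
    return fixture("figure_1")


@pytest.fixture(scope="session")
def fig1_data(fig1):
    return simulate(fig1.dag, fig1.sem, 100_000, seed=20260925)


@pytest.fixture(scope="session")
def fig1_data_50k(fig1):
    return simulate(fig1.dag, fig1.sem, 50_000, seed=11)


@pytest.fixture(scope="session")
def fig6_data():
    entry = fixture("figure_6")
    return simulate(entry.dag, entry.sem, 100_000, seed=3)


@pytest.fixture(scope="session")
def fig8_data():
    entry = fixture("figure_8")
    return simulate(entry.dag, entry.sem, 200_000, seed=5)


@pytest.fixture(scope="session")
def fig9_data():
    entry = fixture("figure_9")
    return simulate(entry.dag, entry.sem, 200_000, seed=7)
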