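"""Annotated causal DAGs: data model, plain-text dialect, validation, queries.

A :class:`Dag` is a directed acyclic graph over named variables, each carrying
one of three node kinds:

``measured``
    an observed variable available as a data column;
``latent``
    an unmeasured variable (e.g. residual confounders, true values of
    mismeasured covariates);
``selection``
    a participation/selection variable conditioned upon during data
    collection (registry membership, restriction to a subgroup).  Selection
    nodes are treated as always-conditioned by every identification query.

A measured node may additionally be declared a *proxy* of a latent node
(``proxy_of``), encoding measurement error: the proxy stands in for the
latent variable and conditioning on it only partially blocks paths through
the latent target.  The implicit measurement-noise parent is represented by
the annotation itself, not by a separate node (an explicit latent noise
parent is also accepted and treated identically).

The plain-text dialect is one statement per line::

    # comment
    node ZU kind=latent
    node "Comorbidity index" proxy_of="Major concurrent illnesses"
    C1 -> A
    "Age" -> "Death"

Edge endpoints that are never declared are implicitly measured nodes.
"""

from __future__ import annotations

import re
import shlex
from dataclasses import dataclass
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "Node",
    "Dag",
    "Query",
    "DagError",
    "DagParseError",
    "parse_dag",
    "write_dag",
    "read_dag",
    "to_dot",
    "ancestors",
    "descendants",
]

NODE_KINDS = ("measured", "latent", "selection")

_PLAIN_NAME = re.compile(r"^[A-Za-z_][A-Za-z0-9_.*+-]*$")


class DagError(ValueError):
    """Invalid DAG structure or annotation."""


class DagParseError(DagError):
    """Syntax or semantic error in a DAG document; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Node:
    """A named variable with its measurement status.

    ``proxy_of`` may only be set on measured nodes and must name a latent
    node of the same graph.
    """

    name: str
    kind: str = "measured"
    proxy_of: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise DagError(f"unknown node kind {self.kind!r} for {self.name!r}")
        if self.proxy_of is not None and self.kind != "measured":
            raise DagError(
                f"proxy_of set on non-measured node {self.name!r} (kind={self.kind})"
            )


class Dag:
    """Validated annotated DAG.

    Parameters
    ----------
    nodes
        Iterable of :class:`Node`; names must be unique.
    edges
        Iterable of ``(tail, head)`` name pairs.  Endpoints not present in
        ``nodes`` are implicitly declared as measured nodes.

    Notes
    -----
    Validation enforces acyclicity, no self-loops/duplicate edges, proxy
    targets existing and latent, and selection nodes having at least one
    parent.  If a proxy node lacks the ``latent -> proxy`` edge it is added
    implicitly (the proxy is by construction a child of its target).
    Iteration order is lexicographic by node name everywhere so that outputs
    are bit-stable.
    """

    def __init__(self, nodes: Iterable[Node] = (), edges: Iterable[tuple[str, str]] = ()):
        node_map: dict[str, Node] = {}
        for node in nodes:
            if node.name in node_map:
                raise DagError(f"duplicate node declaration: {node.name!r}")
            node_map[node.name] = node

        edge_set: set[tuple[str, str]] = set()
        for tail, head in edges:
            if tail == head:
                raise DagError(f"self-loop on {tail!r}")
            if (tail, head) in edge_set:
                raise DagError(f"duplicate edge {tail!r} -> {head!r}")
            edge_set.add((tail, head))
            for name in (tail, head):
                node_map.setdefault(name, Node(name))

        # implicit latent -> proxy edge
        for node in node_map.values():
            if node.proxy_of is not None:
                target = node_map.get(node.proxy_of)
                if target is None:
                    raise DagError(
                        f"proxy node {node.name!r} targets undeclared node {node.proxy_of!r}"
                    )
                if target.kind != "latent":
                    raise DagError(
                        f"proxy node {node.name!r} targets non-latent node {node.proxy_of!r}"
                    )
                edge_set.add((node.proxy_of, node.name))

        self._nodes: dict[str, Node] = {k: node_map[k] for k in sorted(node_map)}
        self._edges: frozenset[tuple[str, str]] = frozenset(edge_set)

        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self._edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise DagError(f"cycle detected: {path}")
        self._graph = g

        for node in self._nodes.values():
            if node.kind == "selection" and g.in_degree(node.name) == 0:
                raise DagError(
                    f"selection node {node.name!r} has no parents; selection nodes "
                    "are conditioned-on descendants of other variables"
                )

        # closure caches; the graph is immutable after construction
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._desc_cache: dict[str, frozenset[str]] = {}

    # -- basic accessors -------------------------------------------------

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    @property
    def nodes(self) -> tuple[Node, ...]:
        return tuple(self._nodes.values())

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(self._edges))

    def node(self, name: str) -> Node:
        try:
            return self._nodes[name]
        except KeyError:
            raise DagError(f"unknown node {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._nodes

    def __iter__(self) -> Iterator[str]:
        return iter(self._nodes)

    def __len__(self) -> int:
        return len(self._nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dag):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((tuple(self._nodes.items()), self._edges))

    def __repr__(self) -> str:
        return f"Dag({len(self._nodes)} nodes, {len(self._edges)} edges)"

    def to_networkx(self) -> nx.DiGraph:
        """Copy of the underlying :class:`networkx.DiGraph` with node kinds."""
        g = self._graph.copy()
        for name, node in self._nodes.items():
            g.nodes[name]["kind"] = node.kind
            if node.proxy_of is not None:
                g.nodes[name]["proxy_of"] = node.proxy_of
        return g

    # -- graph queries ---------------------------------------------------

    def parents(self, name: str) -> tuple[str, ...]:
        self.node(name)
        return tuple(sorted(self._graph.predecessors(name)))

    def children(self, name: str) -> tuple[str, ...]:
        self.node(name)
        return tuple(sorted(self._graph.successors(name)))

    def ancestors(self, name: str) -> frozenset[str]:
        """All strict ancestors of ``name`` (transitive closure, excluding it)."""
        if name not in self._anc_cache:
            self.node(name)
            self._anc_cache[name] = frozenset(nx.ancestors(self._graph, name))
        return self._anc_cache[name]

    def descendants(self, name: str) -> frozenset[str]:
        """All strict descendants of ``name``."""
        if name not in self._desc_cache:
            self.node(name)
            self._desc_cache[name] = frozenset(nx.descendants(self._graph, name))
        return self._desc_cache[name]

    def topological_order(self) -> tuple[str, ...]:
        return tuple(nx.lexicographical_topological_sort(self._graph))

    def selection_nodes(self) -> frozenset[str]:
        return frozenset(n.name for n in self._nodes.values() if n.kind == "selection")

    def latent_nodes(self) -> frozenset[str]:
        return frozenset(n.name for n in self._nodes.values() if n.kind == "latent")

    def measured_nodes(self) -> frozenset[str]:
        return frozenset(n.name for n in self._nodes.values() if n.kind == "measured")

    def proxies_of(self, latent: str) -> frozenset[str]:
        """Measured proxies declared for the latent node ``latent``."""
        return frozenset(
            n.name for n in self._nodes.values() if n.proxy_of == latent
        )

    # -- derived graphs --------------------------------------------------

    def with_edges_removed(self, removed: Iterable[tuple[str, str]]) -> "Dag":
        removed = set(removed)
        keep = [e for e in self._edges if e not in removed]
        # relax selection-parent rule for surgically edited graphs
        nodes = []
        heads = {h for _, h in keep}
        for n in self._nodes.values():
            if n.kind == "selection" and n.name not in heads:
                nodes.append(Node(n.name, "measured", None))
            else:
                nodes.append(n)
        return Dag(nodes, keep)


@dataclass(frozen=True)
class Query:
    """Exposure-outcome pair of interest (the A -> Y effect)."""

    exposure: str
    outcome: str

    def validate(self, dag: Dag) -> None:
        if self.exposure == self.outcome:
            raise DagError("exposure and outcome must differ")
        for name in (self.exposure, self.outcome):
            if dag.node(name).kind != "measured":
                raise DagError(f"query variable {name!r} must be a measured node")


# ---------------------------------------------------------------------------
# dialect parsing / writing


def _quote(name: str) -> str:
    return name if _PLAIN_NAME.match(name) else '"' + name.replace('"', '\\"') + '"'


def parse_dag(text: str) -> Dag:
    """Parse a DAG-dialect document into a validated :class:`Dag`.

    Raises :class:`DagParseError` with the offending line number on syntax
    errors; structural errors (cycles, bad proxy targets) are raised by
    :class:`Dag` validation.
    """
    nodes: list[Node] = []
    declared: set[str] = set()
    edges: list[tuple[str, str]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            tokens = shlex.split(line, comments=True)
        except ValueError as exc:
            raise DagParseError(str(exc), lineno) from None
        if not tokens:
            continue
        if tokens[0] == "node":
            if len(tokens) < 2:
                raise DagParseError("node declaration needs a name", lineno)
            name = tokens[1]
            kind = "measured"
            proxy_of = None
            for tok in tokens[2:]:
                if "=" not in tok:
                    raise DagParseError(f"bad node attribute {tok!r}", lineno)
                key, _, value = tok.partition("=")
                if key == "kind":
                    if value not in NODE_KINDS:
                        raise DagParseError(f"unknown kind {value!r}", lineno)
                    kind = value
                elif key == "proxy_of":
                    proxy_of = value
                else:
                    raise DagParseError(f"unknown node attribute {key!r}", lineno)
            if name in declared:
                raise DagParseError(f"duplicate node declaration {name!r}", lineno)
            declared.add(name)
            try:
                nodes.append(Node(name, kind, proxy_of))
            except DagError as exc:
                raise DagParseError(str(exc), lineno) from None
        elif "->" in tokens:
            if len(tokens) != 3 or tokens[1] != "->":
                raise DagParseError(f"malformed edge statement {line!r}", lineno)
            edges.append((tokens[0], tokens[2]))
        else:
            raise DagParseError(f"unrecognized statement {line!r}", lineno)

    return Dag(nodes, edges)


def write_dag(dag: Dag) -> str:
    """Serialize to the dialect; ``parse_dag(write_dag(d)) == d``."""
    lines: list[str] = []
    edge_names = {n for e in dag.edges for n in e}
    for node in dag.nodes:
        attrs = []
        if node.kind != "measured":
            attrs.append(f"kind={node.kind}")
        if node.proxy_of is not None:
            attrs.append(f"proxy_of={_quote(node.proxy_of)}")
        if attrs or node.name not in edge_names:
            lines.append(" ".join(["node", _quote(node.name), *attrs]))
    for tail, head in dag.edges:
        lines.append(f"{_quote(tail)} -> {_quote(head)}")
    return "\n".join(lines) + ("\n" if lines else "")


def read_dag(path) -> Dag:
    """Read a DAG-dialect file."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_dag(fh.read())


def to_dot(dag: Dag, name: str = "dag") -> str:
    """Graphviz DOT export; selection nodes boxed, latent nodes dashed."""
    def dq(s: str) -> str:
        return '"' + s.replace('"', '\\"') + '"'

    lines = [f"digraph {dq(name)} {{"]
    for node in dag.nodes:
        attrs = [f"kind={dq(node.kind)}"]
        if node.kind == "selection":
            attrs.append("shape=box")
        elif node.kind == "latent":
            attrs.append("style=dashed")
        if node.proxy_of is not None:
            attrs.append(f"proxy_of={dq(node.proxy_of)}")
        lines.append(f"  {dq(node.name)} [{', '.join(attrs)}];")
    for tail, head in dag.edges:
        lines.append(f"  {dq(tail)} -> {dq(head)};")
    lines.append("}")
    return "\n".join(lines) + "\n"


# module-level functional aliases (the operation surface)


def ancestors(dag: Dag, x: str) -> frozenset[str]:
    """Strict ancestors of ``x`` in ``dag``."""
    return dag.ancestors(x)


def descendants(dag: Dag, x: str) -> frozenset[str]:
    """Strict descendants of ``x`` in ``dag``."""
    return dag.descendants(x)
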