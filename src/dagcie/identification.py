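"""Graphical identification: path blocking, d-separation, sufficient sets.

Blocking follows the usual d-separation rules, extended with two
registry-data realities:

* **selection nodes** are appended to every conditioning set (they are
  conditioned upon during data collection);
* **proxy conditioning** of a latent variable (conditioning on a measured
  proxy rather than the latent itself) only *partially* blocks paths on
  which the latent is a non-collider.  A partially blocked noncausal path
  leaves residual bias, so it counts against sufficiency, while for
  d-separation it counts as open (the latent itself is not conditioned).

An adjustment set is *sufficient* for the exposure-outcome effect when,
with the set (plus selection nodes) conditioned, every noncausal path is
fully blocked — the only unblocked paths joining exposure and outcome are
mediating paths.  A *minimally* sufficient set would stop being sufficient
if any member were removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal

from .dag_core import Dag, DagError, Query

__all__ = [
    "PathReport",
    "AdjustmentSet",
    "as_adjustment_set",
    "candidate_pool",
    "proper_paths",
    "all_paths",
    "d_separated",
    "is_sufficient",
    "minimal_sufficient_sets",
    "c_equivalence",
]

AdjustmentSet = frozenset[str]

#: refuse exhaustive subset enumeration beyond this pool size
MAX_CANDIDATE_POOL = 20

PathStatus = Literal["open", "blocked", "partially_blocked"]
PathKlass = Literal["causal", "noncausal"]


def as_adjustment_set(members: Iterable[str]) -> AdjustmentSet:
    return frozenset(members)


@dataclass(frozen=True)
class PathReport:
    """One acyclic path between exposure and outcome with its blocking status.

    ``arrows[i]`` is ``"->"`` when the edge between ``nodes[i]`` and
    ``nodes[i+1]`` points toward the outcome end, else ``"<-"``.
    ``blockers`` are the nodes responsible for the status: full blockers for
    ``blocked`` paths, partially conditioned latents for
    ``partially_blocked`` ones.
    """

    nodes: tuple[str, ...]
    arrows: tuple[str, ...]
    klass: PathKlass
    status: PathStatus
    blockers: tuple[str, ...]

    def __str__(self) -> str:
        text = self.nodes[0]
        for arrow, node in zip(self.arrows, self.nodes[1:]):
            text += ("→" if arrow == "->" else "←") + node
        return text

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "arrows": list(self.arrows),
            "klass": self.klass,
            "status": self.status,
            "blockers": list(self.blockers),
        }


def _enumerate_paths(dag: Dag, x: str, y: str) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All simple paths between x and y in the skeleton, with edge directions."""
    adj: dict[str, set[str]] = {n: set() for n in dag.node_names}
    edges = set(dag.edges)
    for tail, head in edges:
        adj[tail].add(head)
        adj[head].add(tail)

    paths: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    path = [x]
    on_path = {x}

    def walk(node: str) -> None:
        if node == y:
            arrows = tuple(
                "->" if (path[i], path[i + 1]) in edges else "<-"
                for i in range(len(path) - 1)
            )
            paths.append((tuple(path), arrows))
            return
        for nxt in sorted(adj[node]):
            if nxt in on_path:
                continue
            path.append(nxt)
            on_path.add(nxt)
            walk(nxt)
            path.pop()
            on_path.remove(nxt)

    walk(x)
    paths.sort(key=lambda p: (len(p[0]), p[0]))
    return paths


def _classify_path(
    dag: Dag,
    nodes: tuple[str, ...],
    arrows: tuple[str, ...],
    conditioned: frozenset[str],
) -> tuple[PathStatus, tuple[str, ...]]:
    """Blocking status of one path under a conditioning set.

    A collider on the path is open iff it or one of its descendants is
    conditioned.  A conditioned non-collider fully blocks; an unconditioned
    latent non-collider with a conditioned proxy partially blocks.
    """
    full: list[str] = []
    partial: list[str] = []
    for i in range(1, len(nodes) - 1):
        node = nodes[i]
        is_collider = arrows[i - 1] == "->" and arrows[i] == "<-"
        if is_collider:
            opened = node in conditioned or bool(dag.descendants(node) & conditioned)
            if not opened:
                full.append(node)
        else:
            if node in conditioned:
                full.append(node)
            elif dag.node(node).kind == "latent":
                proxies = dag.proxies_of(node)
                if proxies & conditioned:
                    partial.append(node)
    if full:
        return "blocked", tuple(sorted(full))
    if partial:
        return "partially_blocked", tuple(sorted(partial))
    return "open", ()


def _effective_conditioning(dag: Dag, conditioned: Iterable[str]) -> frozenset[str]:
    cond = frozenset(conditioned) | dag.selection_nodes()
    for name in cond:
        dag.node(name)
    return cond


def proper_paths(
    dag: Dag, query: Query, conditioned: Iterable[str] = ()
) -> list[PathReport]:
    """Report every acyclic exposure-outcome path with class and blocking.

    Selection nodes are automatically appended to the conditioning set.
    Conditioning on the exposure or outcome is an error.
    """
    query.validate(dag)
    cond = _effective_conditioning(dag, conditioned)
    if query.exposure in cond or query.outcome in cond:
        raise DagError("cannot condition on the exposure or outcome")
    reports = []
    for nodes, arrows in _enumerate_paths(dag, query.exposure, query.outcome):
        klass: PathKlass = "causal" if all(a == "->" for a in arrows) else "noncausal"
        status, blockers = _classify_path(dag, nodes, arrows, cond)
        reports.append(PathReport(nodes, arrows, klass, status, blockers))
    return reports


def all_paths(dag: Dag, x: str, y: str, given: Iterable[str] = ()) -> list[PathReport]:
    """Like :func:`proper_paths` but for an arbitrary node pair."""
    dag.node(x), dag.node(y)
    cond = _effective_conditioning(dag, given)
    reports = []
    for nodes, arrows in _enumerate_paths(dag, x, y):
        klass: PathKlass = "causal" if all(a == "->" for a in arrows) else "noncausal"
        status, blockers = _classify_path(dag, nodes, arrows, cond)
        reports.append(PathReport(nodes, arrows, klass, status, blockers))
    return reports


def d_separated(dag: Dag, x: str, y: str, given: Iterable[str] = ()) -> bool:
    """True iff every path between ``x`` and ``y`` is fully blocked.

    Selection nodes are auto-appended to ``given``.  Partial blocking via a
    proxy counts as open: conditioning the proxy does not condition the
    latent target.
    """
    given = frozenset(given)
    if x in given or y in given:
        raise DagError("x and y must not be in the conditioning set")
    return all(r.status == "blocked" for r in all_paths(dag, x, y, given))


def candidate_pool(dag: Dag, query: Query) -> tuple[str, ...]:
    """Eligible adjustment variables: measured, non-selection, not the
    exposure/outcome, and not descendants of either."""
    query.validate(dag)
    banned = (
        {query.exposure, query.outcome}
        | dag.descendants(query.exposure)
        | dag.descendants(query.outcome)
    )
    return tuple(
        sorted(
            n
            for n in dag.measured_nodes()
            if n not in banned
        )
    )


def _validate_adjustment_set(dag: Dag, query: Query, s: Iterable[str]) -> AdjustmentSet:
    s = frozenset(s)
    pool = set(candidate_pool(dag, query))
    bad = sorted(s - pool)
    if bad:
        details = []
        desc = dag.descendants(query.exposure) | dag.descendants(query.outcome)
        for name in bad:
            node = dag.node(name)  # raises for unknown names
            if name in (query.exposure, query.outcome):
                details.append(f"{name!r} is the exposure/outcome")
            elif node.kind != "measured":
                details.append(f"{name!r} is {node.kind}")
            elif name in desc:
                details.append(f"{name!r} descends from the exposure or outcome")
            else:  # pragma: no cover - defensive
                details.append(f"{name!r} ineligible")
        raise DagError("invalid adjustment set: " + "; ".join(details))
    return s


def is_sufficient(dag: Dag, query: Query, s: Iterable[str]) -> bool:
    """True iff conditioning on ``s`` (plus selection nodes) fully blocks
    every noncausal exposure-outcome path.

    A partially blocked noncausal path (proxy conditioning) counts as NOT
    blocked.  Sets containing latent/selection nodes or descendants of the
    exposure/outcome raise :class:`~dagcie.dag_core.DagError`.
    """
    s = _validate_adjustment_set(dag, query, s)
    return all(
        r.status == "blocked"
        for r in proper_paths(dag, query, s)
        if r.klass == "noncausal"
    )


def minimal_sufficient_sets(dag: Dag, query: Query) -> list[AdjustmentSet]:
    """All inclusion-minimal sufficient adjustment sets of measured variables.

    Exhaustive over subsets of the candidate pool (the pool is capped at
    ``MAX_CANDIDATE_POOL`` variables); sorted by size then lexicographically.
    An empty list means no sufficient set of measured variables exists.
    """
    pool = candidate_pool(dag, query)
    if len(pool) > MAX_CANDIDATE_POOL:
        raise DagError(
            f"candidate pool has {len(pool)} variables; exhaustive enumeration "
            f"is limited to {MAX_CANDIDATE_POOL}"
        )
    sufficient: list[AdjustmentSet] = []
    for size in range(len(pool) + 1):
        for combo in combinations(pool, size):
            s = frozenset(combo)
            if any(m <= s for m in sufficient):
                continue  # a subset already suffices; s is not minimal
            if is_sufficient(dag, query, s):
                sufficient.append(s)
    sufficient.sort(key=lambda s: (len(s), tuple(sorted(s))))
    return sufficient


def _open_collection(
    dag: Dag, query: Query, s: AdjustmentSet
) -> frozenset[tuple]:
    """Canonical collection of unblocked paths under ``s``.

    Open paths are keyed by (nodes, status); partially blocked paths also
    carry their partial blockers, because shifting where a path is partially
    blocked changes the residual bias it transmits.  Fully blocked paths are
    excluded (their blocker identity is estimand-irrelevant).
    """
    coll = set()
    for r in proper_paths(dag, query, s):
        if r.status == "open":
            coll.add((r.nodes, r.klass, "open"))
        elif r.status == "partially_blocked":
            coll.add((r.nodes, r.klass, "partially_blocked", r.blockers))
    return frozenset(coll)


def _exposure_associated(dag: Dag, query: Query, v: str) -> bool:
    """Is ``v`` marginally d-connected to the exposure (selection conditioned)?

    Used as the qualitative "instrument-like" test for bias amplification:
    adjusting on a variable associated with the exposure re-weights residual
    confounding even when it blocks no additional path.
    """
    if v == query.exposure:
        return True
    return not d_separated(dag, v, query.exposure, ())


def c_equivalence(
    dag: Dag,
    query: Query,
    s: Iterable[str],
    t: Iterable[str],
) -> str:
    """Compare two adjustment sets: do they yield the same adjusted estimand?

    Returns ``"equivalent"``, ``"not_equivalent"``, or
    ``"not_equivalent_amplification"``.  Two sufficient sets are always
    equivalent.  Sets leaving different unblocked-path collections are not
    equivalent.  Sets leaving the *same* nonempty residual noncausal paths
    but differing in exposure-side membership (different instrument
    strengths) are flagged as amplification-inequivalent: the residual bias
    is amplified differently.
    """
    s = _validate_adjustment_set(dag, query, s)
    t = _validate_adjustment_set(dag, query, t)
    coll_s = _open_collection(dag, query, s)
    coll_t = _open_collection(dag, query, t)
    if coll_s != coll_t:
        return "not_equivalent"
    residual_noncausal = {c for c in coll_s if c[1] == "noncausal"}
    if not residual_noncausal:
        return "equivalent"
    assoc_s = frozenset(v for v in s if _exposure_associated(dag, query, v))
    assoc_t = frozenset(v for v in t if _exposure_associated(dag, query, v))
    if assoc_s != assoc_t:
        return "not_equivalent_amplification"
    return "equivalent"
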