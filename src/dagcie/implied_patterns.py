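"""Add-one / minus-one change patterns implied by a DAG.

Given a working adjustment set S, a DAG predicts whether a collapsible
effect estimate should change when re-estimated on S plus each excluded
variable in turn (the *add-one pattern*) or on S minus each member in turn
(the *minus-one pattern*).  A change is implied exactly when the collection
of unblocked (open or partially blocked) exposure-outcome paths differs
between the two conditioning sets — blocking a confounding path, blocking
part of a mediating path, opening a collider path, shifting where a proxy
partially blocks — or when nonempty residual bias paths are re-weighted by
conditioning on an exposure-associated variable (bias amplification).

Whether an implied change is *observed* is decided downstream by the
estimation and workflow modules under the asymmetric weak-faithfulness
rule; this module is purely graph-side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .dag_core import Dag, Query
from .identification import (
    AdjustmentSet,
    _exposure_associated,
    _open_collection,
)

__all__ = [
    "Expectation",
    "ImpliedPattern",
    "CHANGE",
    "NO_CHANGE",
    "AMBIGUOUS",
    "REASONS",
    "eligible_variables",
    "implied_add_one",
    "implied_minus_one",
    "implied_pattern",
    "implied_pattern_signature",
]

CHANGE = "CHANGE"
NO_CHANGE = "NO_CHANGE"
AMBIGUOUS = "AMBIGUOUS"

REASONS = (
    "CONFOUNDER_BLOCKING",
    "MEDIATOR_BLOCKING",
    "COLLIDER_OPENING",
    "PROXY_PARTIAL",
    "BIAS_AMPLIFICATION",
)


@dataclass(frozen=True)
class Expectation:
    verdict: str
    reasons: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.verdict == CHANGE and not self.reasons:
            raise ValueError("CHANGE verdict requires at least one reason")
        if self.verdict == NO_CHANGE and self.reasons:
            raise ValueError("NO_CHANGE verdict must carry no reasons")
        unknown = self.reasons - set(REASONS)
        if unknown:
            raise ValueError(f"unknown reasons {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {"verdict": self.verdict, "reasons": sorted(self.reasons)}


@dataclass(frozen=True)
class ImpliedPattern:
    """Implied change expectations around a base adjustment set."""

    base_set: AdjustmentSet
    add_one: dict[str, Expectation] = field(default_factory=dict)
    minus_one: dict[str, Expectation] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "base_set": sorted(self.base_set),
            "add_one": {v: e.to_dict() for v, e in sorted(self.add_one.items())},
            "minus_one": {v: e.to_dict() for v, e in sorted(self.minus_one.items())},
        }


def eligible_variables(dag: Dag, query: Query) -> tuple[str, ...]:
    """Variables evaluated in add-one sweeps: measured, non-selection,
    other than exposure and outcome.

    Mediators and other descendants of the exposure are included — the
    add-one step conditions on every variable not in S — even though they
    are ineligible for sufficient adjustment sets.
    """
    query.validate(dag)
    return tuple(
        sorted(
            n
            for n in dag.measured_nodes()
            if n not in (query.exposure, query.outcome)
        )
    )


def _expectation_for_transition(
    dag: Dag,
    query: Query,
    before: frozenset[tuple],
    after: frozenset[tuple],
    v: str,
) -> Expectation:
    """Classify the difference between two unblocked-path collections.

    ``before``/``after`` are :func:`_open_collection` results for the
    conditioning sets *without* and *with* ``v`` respectively, so the
    reason codes always describe the role ``v`` plays when conditioned
    (for minus-one patterns the caller passes the depleted set as
    ``before``).
    """
    reasons: set[str] = set()
    before_by_nodes = {c[0]: c for c in before}
    after_by_nodes = {c[0]: c for c in after}

    for nodes, entry in before_by_nodes.items():
        klass, status = entry[1], entry[2]
        after_entry = after_by_nodes.get(nodes)
        if after_entry is None:
            # path became fully blocked
            if status == "partially_blocked":
                reasons.add("PROXY_PARTIAL")
            elif klass == "noncausal":
                reasons.add("CONFOUNDER_BLOCKING")
            else:
                reasons.add("MEDIATOR_BLOCKING")
        elif after_entry != entry:
            reasons.add("PROXY_PARTIAL")

    for nodes, entry in after_by_nodes.items():
        if nodes not in before_by_nodes:
            reasons.add("COLLIDER_OPENING")
        # status changes on shared paths already handled above

    if not reasons:
        residual = {c for c in after if c[1] == "noncausal"}
        if residual and _exposure_associated(dag, query, v):
            reasons.add("BIAS_AMPLIFICATION")

    if reasons:
        return Expectation(CHANGE, frozenset(reasons))
    return Expectation(NO_CHANGE)


def implied_add_one(
    dag: Dag, query: Query, s: Iterable[str]
) -> ImpliedPattern:
    """Expected add-one pattern around ``s``: one verdict per eligible
    variable not in ``s``."""
    s = frozenset(s)
    base = _open_collection(dag, query, s)
    add_one: dict[str, Expectation] = {}
    for v in eligible_variables(dag, query):
        if v in s:
            continue
        after = _open_collection(dag, query, s | {v})
        add_one[v] = _expectation_for_transition(dag, query, base, after, v)
    return ImpliedPattern(base_set=s, add_one=add_one)


def implied_minus_one(
    dag: Dag, query: Query, s: Iterable[str]
) -> ImpliedPattern:
    """Expected minus-one pattern: one verdict per member of ``s``.

    For a minimally sufficient ``s`` every member shows CHANGE; NO_CHANGE
    is possible for non-minimal sets whose remaining members block the same
    paths.
    """
    s = frozenset(s)
    with_v = _open_collection(dag, query, s)
    minus_one: dict[str, Expectation] = {}
    for v in sorted(s):
        without_v = _open_collection(dag, query, s - {v})
        minus_one[v] = _expectation_for_transition(dag, query, without_v, with_v, v)
    return ImpliedPattern(base_set=s, minus_one=minus_one)


def implied_pattern(dag: Dag, query: Query, s: Iterable[str]) -> ImpliedPattern:
    """Full implied pattern (add-one and minus-one) around ``s``."""
    s = frozenset(s)
    return ImpliedPattern(
        base_set=s,
        add_one=implied_add_one(dag, query, s).add_one,
        minus_one=implied_minus_one(dag, query, s).minus_one,
    )


def implied_pattern_signature(
    dag: Dag, query: Query, s: Iterable[str]
) -> tuple[tuple[str, str, str], ...]:
    """Canonical, ordering-stable verdict vector for DAG comparison.

    Two DAGs imply the same patterns at ``s`` iff their signatures are
    equal.  Entries are ``(variable, direction, verdict)`` sorted by
    direction then variable.
    """
    pat = implied_pattern(dag, query, s)
    entries = [("add", v, e.verdict) for v, e in pat.add_one.items()]
    entries += [("minus", v, e.verdict) for v, e in pat.minus_one.items()]
    return tuple(
        (var, direction, verdict)
        for direction, var, verdict in sorted(entries)
    )
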