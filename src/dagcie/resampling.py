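"""Bootstrap stability of add-one/minus-one change patterns.

The point-estimate change classification ignores sampling variability, so
a pattern can flip under resampling.  The nonparametric bootstrap
quantifies this: subjects are resampled with replacement; within each
resample the base estimate and every add-one/minus-one estimate are
refitted, each delta is classified against the threshold rule, and the
per-variable *proportion of resamples beyond the threshold* is reported.

A sensitivity rule treats only add-one variables with proportion > 0.5
(strictly) as showing meaningful changes; minus-one proportions are
reported but never revise the pattern, because an absent implied change is
tolerated under weak faithfulness anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dag_core import Query
from .estimation import (
    ChangeRecord,
    EstimationError,
    ThresholdRule,
    build_design,
)

__all__ = [
    "BootstrapConfig",
    "VariableStability",
    "StabilityReport",
    "bootstrap_stability",
    "apply_majority_rule",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: number of resamples B, seed, threshold rule."""

    n_boot: int = 2000
    seed: int = 0
    rule: ThresholdRule = ThresholdRule("absolute", 0.01)
    cutoff: float = 0.5

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


@dataclass(frozen=True)
class VariableStability:
    """Stability of one add-one/minus-one comparison across resamples."""

    variable: str
    direction: str
    proportion_beyond: float
    n_effective: int
    n_failed: int
    unstable: bool
    deltas: tuple[float, ...]  # |varied - base| per usable resample
    base_points: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "direction": self.direction,
            "proportion_beyond": self.proportion_beyond,
            "n_effective": self.n_effective,
            "n_failed": self.n_failed,
            "unstable": self.unstable,
        }


@dataclass(frozen=True)
class StabilityReport:
    """Per-variable bootstrap proportions for one base adjustment set."""

    base_set: frozenset[str]
    n_boot: int
    seed: int
    rule: ThresholdRule
    entries: dict[tuple[str, str], VariableStability] = field(default_factory=dict)

    def get(self, variable: str, direction: str) -> VariableStability:
        return self.entries[(variable, direction)]

    def proportions(self) -> dict[tuple[str, str], float]:
        return {k: v.proportion_beyond for k, v in sorted(self.entries.items())}

    def reclassify(self, rule: ThresholdRule) -> "StabilityReport":
        """Recompute proportions under a different threshold on the frozen
        resample deltas (no refitting)."""
        entries = {}
        for key, ent in self.entries.items():
            beyond = sum(
                1
                for d, b in zip(ent.deltas, ent.base_points)
                if d > rule.width(b)
            )
            prop = beyond / ent.n_effective if ent.n_effective else 0.0
            entries[key] = replace(ent, proportion_beyond=prop)
        return StabilityReport(self.base_set, self.n_boot, self.seed, rule, entries)

    def to_dict(self) -> dict:
        return {
            "base_set": sorted(self.base_set),
            "n_boot": self.n_boot,
            "seed": self.seed,
            "rule": {"scale": self.rule.scale, "value": self.rule.value},
            "entries": [v.to_dict() for _, v in sorted(self.entries.items())],
        }


def bootstrap_stability(
    data: pd.DataFrame,
    query: Query,
    s: Iterable[str],
    candidates: Sequence[str],
    estimator: str = "RD",
    config: BootstrapConfig = BootstrapConfig(),
) -> StabilityReport:
    """Proportion of resampled add-one/minus-one changes beyond the threshold.

    One shared stream of resample indices is used for every variable so the
    proportions are comparable.  Within each resample the base estimate is
    refitted and each delta taken against it.  Resamples where a fit fails
    are dropped from that variable's denominator; a variable with fewer
    than half of ``n_boot`` usable resamples is flagged unstable.

    Only the RD estimator has a least-squares fast path; RR refits the
    modified-Poisson model per resample and is considerably slower.
    """
    s = frozenset(s)
    candidates = [c for c in candidates if c not in s]
    rng = np.random.default_rng(config.seed)
    n = len(data)
    if n == 0:
        raise EstimationError("empty dataset")

    comparisons: list[tuple[str, str, frozenset[str]]] = [
        *((v, "add", s | {v}) for v in candidates),
        *((v, "minus", s - {v}) for v in sorted(s)),
    ]

    # pre-build full-data designs once; resampling re-indexes the rows
    def design(adj: frozenset[str]):
        X, y, _, _ = build_design(data, query, adj)
        return X, y

    if estimator == "RD":
        base_X, base_y = design(s)
        comp_designs = {}
        for v, direction, adj in comparisons:
            try:
                comp_designs[(v, direction)] = design(adj)
            except EstimationError:
                comp_designs[(v, direction)] = None
    else:
        base_X = base_y = None
        comp_designs = {}

    deltas: dict[tuple[str, str], list[float]] = {
        (v, d): [] for v, d, _ in comparisons
    }
    bases: dict[tuple[str, str], list[float]] = {
        (v, d): [] for v, d, _ in comparisons
    }
    failures: dict[tuple[str, str], int] = {(v, d): 0 for v, d, _ in comparisons}

    from .estimation import _ols_point, estimate_effect

    for _ in range(config.n_boot):
        idx = rng.integers(0, n, size=n)
        if estimator == "RD":
            b = _ols_point(base_X[idx], base_y[idx])
            for v, direction, adj in comparisons:
                dsg = comp_designs[(v, direction)]
                if dsg is None:
                    failures[(v, direction)] += 1
                    continue
                X, y = dsg
                try:
                    point = _ols_point(X[idx], y[idx])
                except np.linalg.LinAlgError:
                    failures[(v, direction)] += 1
                    continue
                deltas[(v, direction)].append(abs(point - b))
                bases[(v, direction)].append(b)
        else:
            resampled = data.iloc[idx]
            try:
                b = estimate_effect(resampled, query, s, estimator).point
            except EstimationError:
                for key in failures:
                    failures[key] += 1
                continue
            for v, direction, adj in comparisons:
                try:
                    point = estimate_effect(resampled, query, adj, estimator).point
                except EstimationError:
                    failures[(v, direction)] += 1
                    continue
                deltas[(v, direction)].append(abs(point - b))
                bases[(v, direction)].append(b)

    entries = {}
    for v, direction, _ in comparisons:
        key = (v, direction)
        ds, bs = deltas[key], bases[key]
        n_eff = len(ds)
        beyond = sum(1 for d, b in zip(ds, bs) if d > config.rule.width(b))
        entries[key] = VariableStability(
            variable=v,
            direction=direction,
            proportion_beyond=beyond / n_eff if n_eff else 0.0,
            n_effective=n_eff,
            n_failed=failures[key],
            unstable=n_eff < config.n_boot / 2,
            deltas=tuple(ds),
            base_points=tuple(bs),
        )
    return StabilityReport(s, config.n_boot, config.seed, config.rule, entries)


def apply_majority_rule(
    observed: Sequence[ChangeRecord],
    stability: StabilityReport,
    cutoff: float = 0.5,
) -> list[ChangeRecord]:
    """Sensitivity revision: add-one records become meaningful iff their
    bootstrap proportion strictly exceeds ``cutoff``; minus-one records
    pass through unchanged."""
    revised = []
    for rec in observed:
        if rec.direction != "add":
            revised.append(rec)
            continue
        key = (rec.variable, "add")
        if key not in stability.entries:
            raise EstimationError(
                f"no stability entry for add-one variable {rec.variable!r}"
            )
        prop = stability.entries[key].proportion_beyond
        revised.append(replace(rec, meaningful=prop > cutoff))
    return revised
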