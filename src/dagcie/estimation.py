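"""Collapsible effect estimation and meaningful-change classification.

The risk difference (RD) is estimated as the exposure coefficient of a
linear probability model (ordinary least squares of the binary outcome on
exposure plus adjustment covariates) with an HC1 heteroskedasticity-
consistent sandwich standard error; the risk ratio (RR) as the
exponentiated exposure coefficient of a modified-Poisson model (GLM with
log link and the same robust variance).  Both are collapsible, which the
add-one/minus-one logic requires — the conditional odds ratio is not and
is deliberately not offered.

A change between two nested (or competing) adjustment sets is *meaningful*
when it exceeds a pre-declared threshold, either absolute
(|delta| > value, e.g. 0.01 on the RD scale) or relative
(|delta| > value * |base|, e.g. a 10% relative difference).  Comparison is
strict; boundary deltas are not meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dag_core import Query
from .identification import AdjustmentSet

__all__ = [
    "EffectEstimate",
    "ThresholdRule",
    "ChangeRecord",
    "EstimationError",
    "ModelFailure",
    "UndefinedChangeError",
    "estimate_effect",
    "classify_change",
    "sweep_add_one",
    "sweep_minus_one",
    "compare_minimal_sets",
    "build_design",
]

_Z95 = float(stats.norm.ppf(0.975))


class EstimationError(ValueError):
    """Invalid estimation inputs."""


class ModelFailure(EstimationError):
    """A regression fit failed (singular design, zero cells, divergence)."""


class UndefinedChangeError(EstimationError):
    """Relative change rule applied with a zero base estimate."""


@dataclass(frozen=True)
class EffectEstimate:
    """Adjusted effect estimate with robust 95% CI.

    ``point`` is on the probability-difference scale for RD and the ratio
    scale for RR; ``se`` is on the estimation scale (log scale for RR).
    """

    estimator: str
    point: float
    se: float
    ci_low: float
    ci_high: float
    n_used: int
    adjustment: AdjustmentSet

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "point": self.point,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_used": self.n_used,
            "adjustment": sorted(self.adjustment),
        }


@dataclass(frozen=True)
class ThresholdRule:
    """Meaningful-change threshold: absolute or relative (fraction, 0.10 = 10%)."""

    scale: str
    value: float

    def __post_init__(self) -> None:
        if self.scale not in ("absolute", "relative"):
            raise EstimationError(f"unknown threshold scale {self.scale!r}")
        if not self.value > 0:
            raise EstimationError("threshold value must be positive")

    def width(self, base: float) -> float:
        """Half-width of the meaningful band around ``base``."""
        if self.scale == "absolute":
            return self.value
        if base == 0:
            raise UndefinedChangeError("relative threshold undefined at base 0")
        return self.value * abs(base)


@dataclass(frozen=True)
class ChangeRecord:
    """One add-one/minus-one (or pairwise) estimate comparison."""

    variable: str
    direction: str  # "add" | "minus" | "pair"
    base: EffectEstimate
    varied: EffectEstimate | None
    delta_abs: float
    delta_rel: float | None
    delta_log: float | None
    meaningful: bool
    usable: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "direction": self.direction,
            "base": self.base.to_dict(),
            "varied": self.varied.to_dict() if self.varied is not None else None,
            "delta_abs": self.delta_abs,
            "delta_rel": self.delta_rel,
            "delta_log": self.delta_log,
            "meaningful": self.meaningful,
            "usable": self.usable,
            "note": self.note,
        }


def classify_change(base: float, varied: float, rule: ThresholdRule) -> bool:
    """Is the move from ``base`` to ``varied`` a meaningful change?

    Strict inequality on |varied - base| against the rule's band width;
    symmetric in the sign of the delta.
    """
    return abs(varied - base) > rule.width(base)


def _check_binary(series: pd.Series, name: str) -> None:
    values = set(series.dropna().unique())
    if not values <= {0, 1, 0.0, 1.0}:
        raise EstimationError(f"column {name!r} must be coded 0/1; got {sorted(values)[:5]}")


def build_design(
    data: pd.DataFrame, query: Query, adjustment: Iterable[str]
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Complete-case design matrix: intercept, exposure, covariate columns.

    Categorical (non-numeric or multi-level integer) covariates expand into
    reference-coded indicator blocks named ``var=level``; a variable is
    always added or removed as its whole block.  Constant columns are
    dropped (they are absorbed by the intercept); a rank-deficient design
    raises :class:`ModelFailure` naming the offending columns.
    """
    adjustment = sorted(set(adjustment))
    missing = [c for c in [query.exposure, query.outcome, *adjustment] if c not in data.columns]
    if missing:
        raise EstimationError(f"columns not in data: {missing}")
    sub = data[[query.outcome, query.exposure, *adjustment]].dropna()
    n_used = len(sub)
    if n_used == 0:
        raise EstimationError("no complete cases")
    _check_binary(sub[query.outcome], query.outcome)
    _check_binary(sub[query.exposure], query.exposure)
    if sub[query.exposure].nunique() < 2:
        raise ModelFailure(f"exposure {query.exposure!r} has a single level in complete cases")

    cols: list[np.ndarray] = [np.ones(n_used), sub[query.exposure].to_numpy(float)]
    names: list[str] = ["const", query.exposure]
    for var in adjustment:
        col = sub[var]
        numeric = pd.api.types.is_numeric_dtype(col)
        levels = col.unique()
        if numeric and (len(levels) <= 2 or not pd.api.types.is_integer_dtype(col)):
            arr = col.to_numpy(float)
            if np.ptp(arr) == 0:
                continue  # constant: absorbed by the intercept
            cols.append(arr)
            names.append(var)
        else:
            dummies = pd.get_dummies(col, drop_first=True)
            for level in dummies.columns:
                arr = dummies[level].to_numpy(float)
                if np.ptp(arr) == 0:
                    continue
                cols.append(arr)
                names.append(f"{var}={level}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of offending columns by greedy scan
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ModelFailure(f"singular design; collinear columns: {bad}")
    y = sub[query.outcome].to_numpy(float)
    return X, y, names, n_used


def _ols_point(X: np.ndarray, y: np.ndarray) -> float:
    """Exposure coefficient by least squares (fast path, no variance)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[1])


def estimate_effect(
    data: pd.DataFrame,
    query: Query,
    adjustment: Iterable[str] = (),
    estimator: str = "RD",
) -> EffectEstimate:
    """Adjusted RD or RR with HC1 sandwich variance and 95% Wald CI.

    Complete-case analysis; ``n_used`` reports the rows actually fitted.
    """
    import statsmodels.api as sm

    if estimator not in ("RD", "RR"):
        raise EstimationError(f"unknown estimator {estimator!r}")
    adjustment = frozenset(adjustment)
    X, y, names, n_used = build_design(data, query, adjustment)

    if estimator == "RD":
        fit = sm.OLS(y, X).fit(cov_type="HC1")
        point = float(fit.params[1])
        se = float(fit.bse[1])
        return EffectEstimate(
            "RD", point, se, point - _Z95 * se, point + _Z95 * se, n_used, adjustment
        )

    # RR: modified Poisson (log link, robust variance)
    for a in (0.0, 1.0):
        if y[X[:, 1] == a].sum() == 0:
            raise ModelFailure(
                f"zero outcome events at exposure={int(a)}; RR undefined"
            )
    try:
        fit = sm.GLM(y, X, family=sm.families.Poisson()).fit(cov_type="HC1", maxiter=200)
    except Exception as exc:  # statsmodels raises several fit errors
        raise ModelFailure(f"log-link fit failed: {exc}") from exc
    if not fit.converged:
        raise ModelFailure("log-link fit did not converge")
    log_point = float(fit.params[1])
    se = float(fit.bse[1])
    point = math.exp(log_point)
    return EffectEstimate(
        "RR",
        point,
        se,
        math.exp(log_point - _Z95 * se),
        math.exp(log_point + _Z95 * se),
        n_used,
        adjustment,
    )


def _make_record(
    variable: str,
    direction: str,
    base: EffectEstimate,
    varied: EffectEstimate,
    rule: ThresholdRule,
) -> ChangeRecord:
    if base.estimator == "RR":
        delta_abs = abs(varied.point - base.point)
        delta_log = abs(math.log(varied.point) - math.log(base.point))
    else:
        delta_abs = abs(varied.point - base.point)
        delta_log = None
    delta_rel = delta_abs / abs(base.point) if base.point != 0 else None
    meaningful = classify_change(base.point, varied.point, rule)
    return ChangeRecord(
        variable, direction, base, varied, delta_abs, delta_rel, delta_log, meaningful
    )


def _failed_record(
    variable: str, direction: str, base: EffectEstimate, exc: Exception
) -> ChangeRecord:
    return ChangeRecord(
        variable,
        direction,
        base,
        None,
        math.nan,
        None,
        None,
        meaningful=False,
        usable=False,
        note=f"fit failed: {exc}",
    )


def sweep_add_one(
    data: pd.DataFrame,
    query: Query,
    s: Iterable[str],
    candidates: Sequence[str],
    estimator: str = "RD",
    rule: ThresholdRule = ThresholdRule("absolute", 0.01),
) -> list[ChangeRecord]:
    """Re-estimate on S plus each candidate in turn; classify each delta.

    A failed fit for one candidate yields an unusable record rather than
    aborting the sweep.
    """
    s = frozenset(s)
    overlap = s & set(candidates)
    if overlap:
        raise EstimationError(f"candidates overlap the base set: {sorted(overlap)}")
    if not candidates:
        return []
    base = estimate_effect(data, query, s, estimator)
    records = []
    for v in candidates:
        try:
            varied = estimate_effect(data, query, s | {v}, estimator)
            records.append(_make_record(v, "add", base, varied, rule))
        except EstimationError as exc:
            records.append(_failed_record(v, "add", base, exc))
    return records


def sweep_minus_one(
    data: pd.DataFrame,
    query: Query,
    s: Iterable[str],
    estimator: str = "RD",
    rule: ThresholdRule = ThresholdRule("absolute", 0.01),
) -> list[ChangeRecord]:
    """Re-estimate on S minus each member in turn; classify each delta."""
    s = frozenset(s)
    if not s:
        return []
    base = estimate_effect(data, query, s, estimator)
    records = []
    for v in sorted(s):
        try:
            varied = estimate_effect(data, query, s - {v}, estimator)
            records.append(_make_record(v, "minus", base, varied, rule))
        except EstimationError as exc:
            records.append(_failed_record(v, "minus", base, exc))
    return records


def compare_minimal_sets(
    data: pd.DataFrame,
    query: Query,
    sets: Sequence[Iterable[str]],
    estimator: str = "RD",
    rule: ThresholdRule = ThresholdRule("absolute", 0.01),
) -> list[ChangeRecord]:
    """Pairwise comparison of estimates over competing sufficient sets.

    All sufficient sets of one DAG are c-equivalent, so a meaningful
    pairwise difference is evidence against that DAG.
    """
    sets = [frozenset(s) for s in sets]
    if len(sets) < 2:
        return []
    estimates = [estimate_effect(data, query, s, estimator) for s in sets]
    records = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            rec = _make_record(
                f"{{{','.join(sorted(sets[i]))}}} vs {{{','.join(sorted(sets[j]))}}}",
                "pair",
                estimates[i],
                estimates[j],
                rule,
            )
            records.append(rec)
    return records
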