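"""The iterative DAG-versus-data procedure and its reporting surface.

The procedure: pick a working DAG from the prior set, find its minimally
sufficient adjustment set, estimate the exposure effect adjusted on that
set and on the add-one/minus-one variations, compare the observed change
pattern with the pattern the DAG implies, and revise toward whichever
prior DAGs are consistent with the data — presenting the prior and all
final DAGs with their estimates.

Consistency is asymmetric ("weak faithfulness"): an observed meaningful
change where the DAG implies none is *inconsistent* (some pathway is
missing or misdrawn); an implied change that is not observed is only
*flagged* — incidental cancellations and sub-threshold effects can hide a
real arrow, so the arrow is retained but labelled for other researchers.
No DAG is ever rejected on flagged loci alone.

Ad hoc DAG editing is out of scope: when no supplied prior DAG is
consistent, the result says so (``unresolved=True``) and lists the
inconsistency loci with the paths the observed changes implicate, to guide
manual revision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .dag_core import Dag, Query
from .estimation import (
    ChangeRecord,
    EffectEstimate,
    EstimationError,
    ThresholdRule,
    compare_minimal_sets,
    estimate_effect,
    sweep_add_one,
    sweep_minus_one,
)
from .identification import AdjustmentSet, minimal_sufficient_sets
from .implied_patterns import (
    CHANGE,
    NO_CHANGE,
    ImpliedPattern,
    eligible_variables,
    implied_pattern,
)
from .resampling import BootstrapConfig, StabilityReport, apply_majority_rule, bootstrap_stability

__all__ = [
    "OK",
    "INCONSISTENT",
    "FLAGGED_WEAK_FAITHFULNESS",
    "ConsistencyReport",
    "CandidateEvaluation",
    "WorkflowConfig",
    "WorkflowResult",
    "check_consistency",
    "evaluate_candidate",
    "screen_candidates",
    "run_workflow",
    "render_pattern_plot",
]

OK = "OK"
INCONSISTENT = "INCONSISTENT"
FLAGGED_WEAK_FAITHFULNESS = "FLAGGED_WEAK_FAITHFULNESS"


@dataclass(frozen=True)
class ConsistencyReport:
    """Implied-vs-observed verdicts for one DAG at one adjustment set."""

    verdicts: dict[tuple[str, str], str]  # (variable, direction) -> verdict
    dag_verdict: str  # "consistent" | "inconsistent"
    inconsistency_loci: tuple[tuple[str, str], ...]
    flagged_loci: tuple[tuple[str, str], ...]
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "verdicts": {f"{d}:{v}": verdict for (v, d), verdict in sorted(self.verdicts.items())},
            "dag_verdict": self.dag_verdict,
            "inconsistency_loci": [list(x) for x in self.inconsistency_loci],
            "flagged_loci": [list(x) for x in self.flagged_loci],
            "notes": list(self.notes),
        }


def check_consistency(
    implied: ImpliedPattern, observed: Sequence[ChangeRecord]
) -> ConsistencyReport:
    """Compare an implied pattern with observed change records.

    Per variable: implied NO_CHANGE with an observed meaningful change is
    INCONSISTENT; implied CHANGE without an observed meaningful change is
    FLAGGED_WEAK_FAITHFULNESS (the arrow is retained, labelled); matches
    are OK.  Amplification-reasoned CHANGE is matched like any CHANGE.
    The DAG verdict is consistent iff there is no INCONSISTENT locus;
    flagged loci never make a DAG inconsistent.
    """
    obs = {(r.variable, r.direction): r for r in observed}
    verdicts: dict[tuple[str, str], str] = {}
    notes = []
    for direction, mapping in (("add", implied.add_one), ("minus", implied.minus_one)):
        for variable, expectation in mapping.items():
            key = (variable, direction)
            if key not in obs:
                raise EstimationError(
                    f"no observed {direction}-one record for variable {variable!r}"
                )
            rec = obs[key]
            if not rec.usable:
                verdicts[key] = OK
                notes.append(f"{direction}:{variable} unusable fit; not scored")
                continue
            if expectation.verdict == NO_CHANGE and rec.meaningful:
                verdicts[key] = INCONSISTENT
            elif expectation.verdict == CHANGE and not rec.meaningful:
                verdicts[key] = FLAGGED_WEAK_FAITHFULNESS
            else:
                verdicts[key] = OK
    inconsistent = tuple(sorted(k for k, v in verdicts.items() if v == INCONSISTENT))
    flagged = tuple(sorted(k for k, v in verdicts.items() if v == FLAGGED_WEAK_FAITHFULNESS))
    return ConsistencyReport(
        verdicts=verdicts,
        dag_verdict="inconsistent" if inconsistent else "consistent",
        inconsistency_loci=inconsistent,
        flagged_loci=flagged,
        notes=tuple(notes),
    )


@dataclass(frozen=True)
class WorkflowConfig:
    """Run configuration for candidate screening and iteration."""

    estimator: str = "RD"
    rule: ThresholdRule = ThresholdRule("absolute", 0.01)
    bootstrap: BootstrapConfig | None = None
    max_iterations: int = 10


@dataclass(frozen=True)
class CandidateEvaluation:
    """Everything computed for one candidate DAG."""

    name: str
    dag: Dag
    minimal_sets: tuple[AdjustmentSet, ...]
    working_set: AdjustmentSet
    no_sufficient_set: bool
    base_estimate: EffectEstimate
    add_one: tuple[ChangeRecord, ...]
    minus_one: tuple[ChangeRecord, ...]
    implied: ImpliedPattern
    consistency: ConsistencyReport
    cross_set_records: tuple[ChangeRecord, ...]
    cross_set_inconsistent: bool
    stability: StabilityReport | None
    consistency_majority: ConsistencyReport | None

    @property
    def consistent(self) -> bool:
        return (
            self.consistency.dag_verdict == "consistent"
            and not self.cross_set_inconsistent
        )

    @property
    def n_flagged(self) -> int:
        return len(self.consistency.flagged_loci)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "minimal_sets": [sorted(s) for s in self.minimal_sets],
            "working_set": sorted(self.working_set),
            "no_sufficient_set": self.no_sufficient_set,
            "base_estimate": self.base_estimate.to_dict(),
            "add_one": [r.to_dict() for r in self.add_one],
            "minus_one": [r.to_dict() for r in self.minus_one],
            "implied": self.implied.to_dict(),
            "consistency": self.consistency.to_dict(),
            "cross_set_records": [r.to_dict() for r in self.cross_set_records],
            "cross_set_inconsistent": self.cross_set_inconsistent,
            "stability": self.stability.to_dict() if self.stability else None,
            "consistency_majority": (
                self.consistency_majority.to_dict() if self.consistency_majority else None
            ),
            "consistent": self.consistent,
        }


def evaluate_candidate(
    name: str,
    dag: Dag,
    query: Query,
    data: pd.DataFrame,
    config: WorkflowConfig,
    fallback_set: AdjustmentSet = frozenset(),
) -> CandidateEvaluation:
    """Run the per-DAG steps: minimal set, sweeps, implied pattern,
    consistency, cross-minimal-set comparison, optional bootstrap.

    The working set is the lexicographically first smallest minimal
    sufficient set; a DAG with no sufficient set of measured variables is
    evaluated on ``fallback_set`` and flagged.
    """
    msets = tuple(minimal_sufficient_sets(dag, query))
    if msets:
        working = msets[0]
        no_sufficient = False
    else:
        working = frozenset(fallback_set)
        no_sufficient = True

    candidates = [
        v for v in eligible_variables(dag, query)
        if v not in working and v in data.columns
    ]
    base = estimate_effect(data, query, working, config.estimator)
    add_records = sweep_add_one(data, query, working, candidates, config.estimator, config.rule)
    minus_records = sweep_minus_one(data, query, working, config.estimator, config.rule)

    implied = implied_pattern(dag, query, working)
    # restrict the implied pattern to variables observable in the data
    implied = ImpliedPattern(
        base_set=implied.base_set,
        add_one={v: e for v, e in implied.add_one.items() if v in data.columns},
        minus_one={v: e for v, e in implied.minus_one.items() if v in data.columns},
    )
    consistency = check_consistency(implied, [*add_records, *minus_records])
    if no_sufficient:
        consistency = ConsistencyReport(
            verdicts=consistency.verdicts,
            dag_verdict=consistency.dag_verdict,
            inconsistency_loci=consistency.inconsistency_loci,
            flagged_loci=consistency.flagged_loci,
            notes=(*consistency.notes,
                   "no sufficient adjustment set of measured variables; "
                   "evaluated on the supplied fallback set"),
        )

    cross = tuple(
        compare_minimal_sets(data, query, list(msets), config.estimator, config.rule)
    ) if len(msets) >= 2 else ()
    cross_bad = any(r.meaningful for r in cross if r.usable)

    stability = None
    consistency_majority = None
    if config.bootstrap is not None and config.bootstrap.n_boot > 0:
        boot = BootstrapConfig(
            n_boot=config.bootstrap.n_boot,
            seed=config.bootstrap.seed,
            rule=config.rule,
            cutoff=config.bootstrap.cutoff,
        )
        stability = bootstrap_stability(
            data, query, working, candidates, config.estimator, boot
        )
        revised = apply_majority_rule(
            [*add_records, *minus_records], stability, boot.cutoff
        )
        consistency_majority = check_consistency(implied, revised)

    return CandidateEvaluation(
        name=name,
        dag=dag,
        minimal_sets=msets,
        working_set=working,
        no_sufficient_set=no_sufficient,
        base_estimate=base,
        add_one=tuple(add_records),
        minus_one=tuple(minus_records),
        implied=implied,
        consistency=consistency,
        cross_set_records=cross,
        cross_set_inconsistent=cross_bad,
        stability=stability,
        consistency_majority=consistency_majority,
    )


def screen_candidates(
    candidates: Mapping[str, Dag],
    query: Query,
    data: pd.DataFrame,
    config: WorkflowConfig = WorkflowConfig(),
    fallback_set: AdjustmentSet = frozenset(),
) -> list[CandidateEvaluation]:
    """Evaluate every candidate DAG on its own minimal set.

    Observed patterns are recomputed per candidate (each candidate's own
    working set), and candidates with two or more minimal sets are
    additionally checked for cross-set c-equivalence in the data.
    """
    if not candidates:
        raise ValueError("at least one candidate DAG is required")
    evaluations = []
    for name in candidates:
        dag = candidates[name]
        query.validate(dag)
        evaluations.append(
            evaluate_candidate(name, dag, query, data, config, fallback_set)
        )
    return evaluations


@dataclass(frozen=True)
class WorkflowResult:
    """Outcome of the full iterative procedure."""

    query: Query
    prior_working: str
    evaluations: dict[str, CandidateEvaluation]
    final_dags: tuple[str, ...]
    all_consistent: tuple[str, ...]
    unresolved: bool
    iteration_log: tuple[str, ...]

    def final_evaluations(self) -> list[CandidateEvaluation]:
        return [self.evaluations[n] for n in self.final_dags]

    def to_dict(self) -> dict:
        return {
            "exposure": self.query.exposure,
            "outcome": self.query.outcome,
            "prior_working": self.prior_working,
            "evaluations": {n: e.to_dict() for n, e in sorted(self.evaluations.items())},
            "final_dags": list(self.final_dags),
            "all_consistent": list(self.all_consistent),
            "unresolved": self.unresolved,
            "iteration_log": list(self.iteration_log),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def run_workflow(
    prior_dags: Mapping[str, Dag],
    working: str,
    query: Query,
    data: pd.DataFrame,
    config: WorkflowConfig = WorkflowConfig(),
) -> WorkflowResult:
    """Iterate the procedure over the supplied prior DAGs.

    Starting from the chosen working DAG, candidates are evaluated (each on
    its own minimal set, memoized), inconsistent ones dropped, and the
    process repeats until the retained set is stable or the iteration bound
    is hit.  ``final_dags`` are the consistent DAGs preferring those with
    no weak-faithfulness flags (all consistent DAGs remain reported in
    ``all_consistent``); ``unresolved`` is True when no prior DAG is
    consistent — the result then lists every inconsistency locus rather
    than inventing DAG edits.
    """
    if working not in prior_dags:
        raise ValueError(f"working DAG {working!r} not among the priors")
    log: list[str] = [f"start: working DAG {working!r}, priors {sorted(prior_dags)}"]

    evaluations: dict[str, CandidateEvaluation] = {}
    # fallback set for DAGs with no sufficient measured set: the working
    # DAG's own minimal set if it has one
    working_eval = evaluate_candidate(
        working, prior_dags[working], query, data, config
    )
    evaluations[working] = working_eval
    log.append(
        f"evaluated {working!r}: working set {sorted(working_eval.working_set)}, "
        f"{working_eval.consistency.dag_verdict}"
    )
    fallback = working_eval.working_set

    active = set(prior_dags)
    for iteration in range(config.max_iterations):
        changed = False
        for name in sorted(active):
            if name not in evaluations:
                evaluations[name] = evaluate_candidate(
                    name, prior_dags[name], query, data, config, fallback
                )
                log.append(
                    f"evaluated {name!r}: working set "
                    f"{sorted(evaluations[name].working_set)}, "
                    f"{evaluations[name].consistency.dag_verdict}"
                )
                changed = True
        drop = {n for n in active if not evaluations[n].consistent}
        if drop:
            for n in sorted(drop):
                loci = evaluations[n].consistency.inconsistency_loci
                extra = " (cross-set disagreement)" if evaluations[n].cross_set_inconsistent else ""
                log.append(f"iteration {iteration}: dropped {n!r} at {list(loci)}{extra}")
            active -= drop
            changed = True
        if not changed:
            break
    log.append(f"retained after iteration: {sorted(active)}")

    consistent = tuple(sorted(active))
    unflagged = tuple(
        n for n in consistent
        if evaluations[n].n_flagged == 0 and not evaluations[n].no_sufficient_set
    )
    final = unflagged if unflagged else consistent
    if unflagged and len(unflagged) < len(consistent):
        log.append(
            f"preferring flag-free DAGs {list(unflagged)}; "
            f"also consistent (with weak-faithfulness flags): "
            f"{[n for n in consistent if n not in unflagged]}"
        )
    unresolved = not consistent
    if unresolved:
        log.append("none of the prior DAGs is consistent with the observed patterns")
    return WorkflowResult(
        query=query,
        prior_working=working,
        evaluations=evaluations,
        final_dags=final,
        all_consistent=consistent,
        unresolved=unresolved,
        iteration_log=tuple(log),
    )


# ---------------------------------------------------------------------------
# plotting


def render_pattern_plot(
    base: EffectEstimate,
    records: Sequence[ChangeRecord],
    rules: Sequence[ThresholdRule],
    out=None,
    ax=None,
    title: str | None = None,
):
    """Add-one/minus-one pattern plot.

    Solid horizontal line: the base estimate; per rule a pair of horizontal
    guides (dotted for absolute, dashed for relative); one point with 95%
    CI whiskers per change record, add-one section left of the divider,
    minus-one right.  Returns the matplotlib Axes; writes ``out`` if given.
    """
    import matplotlib
    if out is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not records:
        raise ValueError("at least one change record is required")
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(records) + 3, 4.5))

    adds = [r for r in records if r.direction == "add"]
    minuses = [r for r in records if r.direction == "minus"]
    ordered = adds + minuses
    xs = range(len(ordered))

    ax.axhline(base.point, color="black", lw=1.5)
    for rule in rules:
        width = rule.width(base.point)
        style = ":" if rule.scale == "absolute" else "--"
        for sign in (+1, -1):
            ax.axhline(base.point + sign * width, color="grey", ls=style, lw=1)
    for x, rec in zip(xs, ordered):
        if rec.varied is None:
            continue
        ax.errorbar(
            x,
            rec.varied.point,
            yerr=[[rec.varied.point - rec.varied.ci_low], [rec.varied.ci_high - rec.varied.point]],
            fmt="o",
            color="tab:red" if rec.meaningful else "tab:blue",
            capsize=3,
        )
    if adds and minuses:
        ax.axvline(len(adds) - 0.5, color="black", lw=0.8, alpha=0.5)
    sections = [f"+{r.variable}" for r in adds] + [f"-{r.variable}" for r in minuses]
    ax.set_xticks(list(xs))
    ax.set_xticklabels(sections, rotation=45, ha="right")
    ax.set_ylabel(f"{base.estimator} estimate")
    ax.set_title(title or f"Add-one / minus-one pattern (base {{{', '.join(sorted(base.adjustment))}}})")
    ax.figure.tight_layout()
    if out is not None:
        ax.figure.savefig(out)
        plt.close(ax.figure)
    return ax
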