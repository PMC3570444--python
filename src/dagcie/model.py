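"""Model/Results surface over the pattern-comparison machinery.

Two entry points, styled after statsmodels:

* :class:`ChangeInEstimateAnalysis` — one DAG against one dataset; ``fit``
  runs the adjusted estimate, the add-one/minus-one sweeps, the implied
  pattern, the consistency check, and (optionally) the bootstrap, and
  returns a :class:`ChangeInEstimateResults` with a ``summary()`` table
  and ``plot()``.
* :class:`AdjustmentSelection` — a set of candidate prior DAGs; ``fit``
  runs the full iterative selection and returns
  :class:`AdjustmentSelectionResults`.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .dag_core import Dag, Query
from .estimation import ThresholdRule
from .identification import minimal_sufficient_sets
from .resampling import BootstrapConfig
from .workflow import (
    CandidateEvaluation,
    WorkflowConfig,
    WorkflowResult,
    evaluate_candidate,
    render_pattern_plot,
    run_workflow,
)

__all__ = [
    "ChangeInEstimateAnalysis",
    "ChangeInEstimateResults",
    "AdjustmentSelection",
    "AdjustmentSelectionResults",
]


class ChangeInEstimateAnalysis:
    """Change-in-estimate pattern analysis of one DAG on one dataset.

    Parameters
    ----------
    data : DataFrame
        Subject-level data; binary outcome and exposure coded 0/1.
    dag : Dag
        The working causal diagram.
    exposure, outcome : str
        Names of the exposure and outcome variables.
    adjustment : iterable of str, optional
        Working adjustment set; defaults to the lexicographically first
        smallest minimally sufficient set of the DAG.
    estimator : {"RD", "RR"}
    rule : ThresholdRule
        Meaningful-change threshold (default: absolute 0.01).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dag: Dag,
        exposure: str,
        outcome: str,
        adjustment: Iterable[str] | None = None,
        estimator: str = "RD",
        rule: ThresholdRule = ThresholdRule("absolute", 0.01),
    ):
        self.data = data
        self.dag = dag
        self.query = Query(exposure, outcome)
        self.query.validate(dag)
        self.estimator = estimator
        self.rule = rule
        self._adjustment = frozenset(adjustment) if adjustment is not None else None

    def fit(self, bootstrap: BootstrapConfig | None = None) -> "ChangeInEstimateResults":
        config = WorkflowConfig(
            estimator=self.estimator, rule=self.rule, bootstrap=bootstrap
        )
        if self._adjustment is not None:
            evaluation = _evaluate_with_set(
                self.dag, self.query, self.data, config, self._adjustment
            )
        else:
            evaluation = evaluate_candidate(
                "working", self.dag, self.query, self.data, config
            )
        return ChangeInEstimateResults(self, evaluation)


def _evaluate_with_set(dag, query, data, config, adjustment) -> CandidateEvaluation:
    """Evaluate on a user-supplied working set instead of the derived one."""
    from .estimation import estimate_effect, sweep_add_one, sweep_minus_one
    from .implied_patterns import ImpliedPattern, eligible_variables, implied_pattern
    from .workflow import check_consistency

    msets = tuple(minimal_sufficient_sets(dag, query))
    candidates = [
        v for v in eligible_variables(dag, query)
        if v not in adjustment and v in data.columns
    ]
    base = estimate_effect(data, query, adjustment, config.estimator)
    add_records = sweep_add_one(data, query, adjustment, candidates, config.estimator, config.rule)
    minus_records = sweep_minus_one(data, query, adjustment, config.estimator, config.rule)
    implied = implied_pattern(dag, query, adjustment)
    implied = ImpliedPattern(
        base_set=implied.base_set,
        add_one={v: e for v, e in implied.add_one.items() if v in data.columns},
        minus_one={v: e for v, e in implied.minus_one.items() if v in data.columns},
    )
    consistency = check_consistency(implied, [*add_records, *minus_records])

    stability = None
    consistency_majority = None
    if config.bootstrap is not None and config.bootstrap.n_boot > 0:
        from .resampling import apply_majority_rule, bootstrap_stability

        boot = BootstrapConfig(
            n_boot=config.bootstrap.n_boot,
            seed=config.bootstrap.seed,
            rule=config.rule,
            cutoff=config.bootstrap.cutoff,
        )
        stability = bootstrap_stability(
            data, query, adjustment, candidates, config.estimator, boot
        )
        revised = apply_majority_rule([*add_records, *minus_records], stability, boot.cutoff)
        consistency_majority = check_consistency(implied, revised)

    return CandidateEvaluation(
        name="working",
        dag=dag,
        minimal_sets=msets,
        working_set=frozenset(adjustment),
        no_sufficient_set=not msets,
        base_estimate=base,
        add_one=tuple(add_records),
        minus_one=tuple(minus_records),
        implied=implied,
        consistency=consistency,
        cross_set_records=(),
        cross_set_inconsistent=False,
        stability=stability,
        consistency_majority=consistency_majority,
    )


class ChangeInEstimateResults:
    """Fitted pattern analysis: estimates, verdicts, stability."""

    def __init__(self, model: ChangeInEstimateAnalysis, evaluation: CandidateEvaluation):
        self.model = model
        self.evaluation = evaluation

    # convenience accessors ------------------------------------------------
    @property
    def base_estimate(self):
        return self.evaluation.base_estimate

    @property
    def add_one(self):
        return self.evaluation.add_one

    @property
    def minus_one(self):
        return self.evaluation.minus_one

    @property
    def implied(self):
        return self.evaluation.implied

    @property
    def consistency(self):
        return self.evaluation.consistency

    @property
    def stability(self):
        return self.evaluation.stability

    @property
    def consistent(self) -> bool:
        return self.evaluation.consistent

    def records_frame(self) -> pd.DataFrame:
        """Change records as a tidy DataFrame."""
        rows = []
        for rec in [*self.add_one, *self.minus_one]:
            implied_map = (
                self.implied.add_one if rec.direction == "add" else self.implied.minus_one
            )
            exp = implied_map.get(rec.variable)
            prop = None
            if self.stability is not None:
                ent = self.stability.entries.get((rec.variable, rec.direction))
                prop = ent.proportion_beyond if ent else None
            rows.append(
                {
                    "variable": rec.variable,
                    "direction": rec.direction,
                    "estimate": rec.varied.point if rec.varied else float("nan"),
                    "delta_abs": rec.delta_abs,
                    "meaningful": rec.meaningful,
                    "implied": exp.verdict if exp else None,
                    "verdict": self.consistency.verdicts.get((rec.variable, rec.direction)),
                    "boot_proportion": prop,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        ev = self.evaluation
        b = ev.base_estimate
        lines = [
            "Change-in-estimate pattern analysis",
            "=" * 72,
            f"Exposure: {self.model.query.exposure}    Outcome: {self.model.query.outcome}",
            f"Estimator: {b.estimator}    n used: {b.n_used}",
            f"Working adjustment set: {{{', '.join(sorted(ev.working_set)) or '-'}}}",
            f"Minimal sufficient sets: "
            + (
                "; ".join("{" + ", ".join(sorted(s)) + "}" for s in ev.minimal_sets)
                or "none (no sufficient set of measured variables)"
            ),
            f"Base estimate: {b.point:.4f} (95% CI {b.ci_low:.4f}, {b.ci_high:.4f})",
            f"Threshold: {self.model.rule.scale} {self.model.rule.value}",
            "-" * 72,
            f"{'dir':<6}{'variable':<28}{'estimate':>10}{'delta':>9}"
            f"{'meaningful':>11}{'implied':>10}{'verdict':>10}",
        ]
        frame = self.records_frame()
        for _, row in frame.iterrows():
            verdict = {
                "OK": "ok",
                "INCONSISTENT": "INCONSIST",
                "FLAGGED_WEAK_FAITHFULNESS": "flagged",
                None: "-",
            }[row["verdict"]]
            lines.append(
                f"{row['direction']:<6}{row['variable']:<28}"
                f"{row['estimate']:>10.4f}{row['delta_abs']:>9.4f}"
                f"{str(bool(row['meaningful'])):>11}"
                f"{(row['implied'] or '-'):>10}{verdict:>10}"
            )
        lines.append("-" * 72)
        lines.append(f"DAG verdict: {ev.consistency.dag_verdict}")
        if ev.stability is not None:
            lines.append(
                f"Bootstrap: B={ev.stability.n_boot}, seed={ev.stability.seed}; "
                "proportions beyond threshold per variable:"
            )
            for (v, d), ent in sorted(ev.stability.entries.items()):
                lines.append(f"  {d:<6}{v:<28}{100 * ent.proportion_beyond:6.1f}%")
        return "\n".join(lines)

    def plot(self, out=None, ax=None, rules=None):
        rules = rules if rules is not None else [self.model.rule]
        return render_pattern_plot(
            self.base_estimate,
            [*self.add_one, *self.minus_one],
            rules,
            out=out,
            ax=ax,
        )


class AdjustmentSelection:
    """Iterative DAG screening over a set of candidate prior DAGs."""

    def __init__(
        self,
        data: pd.DataFrame,
        prior_dags: Mapping[str, Dag],
        working: str,
        exposure: str,
        outcome: str,
        estimator: str = "RD",
        rule: ThresholdRule = ThresholdRule("absolute", 0.01),
        bootstrap: BootstrapConfig | None = None,
        max_iterations: int = 10,
    ):
        self.data = data
        self.prior_dags = dict(prior_dags)
        self.working = working
        self.query = Query(exposure, outcome)
        self.config = WorkflowConfig(
            estimator=estimator,
            rule=rule,
            bootstrap=bootstrap,
            max_iterations=max_iterations,
        )

    def fit(self) -> "AdjustmentSelectionResults":
        result = run_workflow(
            self.prior_dags, self.working, self.query, self.data, self.config
        )
        return AdjustmentSelectionResults(self, result)


class AdjustmentSelectionResults:
    """Outcome of the iterative selection with reporting helpers."""

    def __init__(self, model: AdjustmentSelection, result: WorkflowResult):
        self.model = model
        self.result = result

    @property
    def final_dags(self) -> tuple[str, ...]:
        return self.result.final_dags

    @property
    def unresolved(self) -> bool:
        return self.result.unresolved

    def summary(self) -> str:
        res = self.result
        lines = [
            "DAG-informed adjustment-variable selection",
            "=" * 72,
            f"Exposure: {res.query.exposure}    Outcome: {res.query.outcome}",
            f"Prior working DAG: {res.prior_working}",
            f"Candidate DAGs: {', '.join(sorted(res.evaluations))}",
            "-" * 72,
        ]
        for name, ev in sorted(res.evaluations.items()):
            b = ev.base_estimate
            status = "CONSISTENT" if ev.consistent else "inconsistent"
            lines.append(
                f"{name:<16} set {{{', '.join(sorted(ev.working_set)) or '-'}}}: "
                f"{b.estimator} {b.point:+.4f} "
                f"(95% CI {b.ci_low:+.4f}, {b.ci_high:+.4f})  [{status}"
                + (f", {ev.n_flagged} flagged" if ev.n_flagged else "")
                + (", no sufficient set" if ev.no_sufficient_set else "")
                + "]"
            )
        lines.append("-" * 72)
        if res.unresolved:
            lines.append(
                "No prior DAG is consistent with the observed patterns; revise "
                "the prior DAG set (inconsistency loci in the iteration log)."
            )
        else:
            lines.append(f"Final DAG(s): {', '.join(res.final_dags)}")
            extra = [n for n in res.all_consistent if n not in res.final_dags]
            if extra:
                lines.append(
                    f"Also consistent under weak faithfulness (flagged loci): "
                    f"{', '.join(extra)}"
                )
        return "\n".join(lines)

    def to_json(self, path) -> None:
        self.result.to_json(path)
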