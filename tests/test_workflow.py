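"""Consistency checking, candidate screening, the full procedure, plotting."""

import numpy as np
import pytest

from dagcie.dag_core import Query
from dagcie.estimation import ThresholdRule, sweep_add_one, sweep_minus_one
from dagcie.implied_patterns import implied_pattern
from dagcie.synthetic_data import fixture, simulate
from dagcie.workflow import (
    FLAGGED_WEAK_FAITHFULNESS,
    INCONSISTENT,
    OK,
    WorkflowConfig,
    check_consistency,
    render_pattern_plot,
    run_workflow,
    screen_candidates,
)

Q = Query("A", "Y")
ABS_RULE = ThresholdRule("absolute", 0.01)
CONFIG = WorkflowConfig(estimator="RD", rule=ABS_RULE, bootstrap=None)


@pytest.fixture(scope="module")
def fig1_observed_at_c1(fig1_data):
    adds = sweep_add_one(fig1_data, Q, {"C1"}, ["C2", "C3", "C4", "C5"], rule=ABS_RULE)
    minus = sweep_minus_one(fig1_data, Q, {"C1"}, rule=ABS_RULE)
    return adds + minus


class TestCheckConsistency:
    def test_figure_2_rejected_at_c2_c3(self, fig1_observed_at_c1):
        implied = implied_pattern(fixture("figure_2").dag, Q, {"C1"})
        report = check_consistency(implied, fig1_observed_at_c1)
        assert report.dag_verdict == "inconsistent"
        assert report.inconsistency_loci == (("C2", "add"), ("C3", "add"))

    def test_figure_3_consistent_with_same_observations(self, fig1_observed_at_c1):
        implied = implied_pattern(fixture("figure_3").dag, Q, {"C1"})
        report = check_consistency(implied, fig1_observed_at_c1)
        assert report.dag_verdict == "consistent"
        assert report.inconsistency_loci == ()

    def test_unobserved_implied_change_only_flags(self, fig1, fig1_data):
        # base set {C1,C2,C3}: removing C2 or C3 changes nothing in the
        # data, but figure_3 implies changes -> flagged, not inconsistent
        implied = implied_pattern(fixture("figure_3").dag, Q, {"C1", "C2", "C3"})
        adds = sweep_add_one(fig1_data, Q, {"C1", "C2", "C3"}, ["C4", "C5"], rule=ABS_RULE)
        minus = sweep_minus_one(fig1_data, Q, {"C1", "C2", "C3"}, rule=ABS_RULE)
        report = check_consistency(implied, adds + minus)
        assert report.dag_verdict == "consistent"
        assert ("C2", "minus") in report.flagged_loci
        assert ("C3", "minus") in report.flagged_loci

    def test_missing_observation_is_an_error(self, fig1_observed_at_c1):
        implied = implied_pattern(fixture("figure_1").dag, Q, {"C1", "C2"})
        with pytest.raises(Exception, match="C3"):
            check_consistency(implied, [r for r in fig1_observed_at_c1 if r.variable == "C4"])


class TestScreenCandidates:
    def test_partition_on_figure_1_data(self, fig1_data):
        candidates = {n: fixture(n).dag for n in ("figure_1", "figure_2", "figure_3", "figure_4")}
        evaluations = screen_candidates(candidates, Q, fig1_data, CONFIG)
        by_name = {e.name: e for e in evaluations}
        assert by_name["figure_1"].consistent
        assert by_name["figure_3"].consistent  # flagged minus-one only
        assert by_name["figure_3"].n_flagged == 2
        assert not by_name["figure_2"].consistent
        assert not by_name["figure_4"].consistent
        # figure_4 is excluded at C3 specifically
        assert ("C3", "add") in by_name["figure_4"].consistency.inconsistency_loci

    def test_candidate_identical_to_truth_is_consistent(self, fig1_data):
        (ev,) = screen_candidates({"truth": fixture("figure_1").dag}, Q, fig1_data, CONFIG)
        assert ev.consistent and ev.n_flagged == 0

    def test_cross_minimal_set_check_runs(self, fig1_data):
        (ev,) = screen_candidates({"truth": fixture("figure_1").dag}, Q, fig1_data, CONFIG)
        assert len(ev.cross_set_records) == 1
        assert not ev.cross_set_inconsistent

    def test_no_sufficient_set_candidate_flagged(self, fig8_data):
        (ev,) = screen_candidates(
            {"fig8": fixture("figure_8").dag}, Q, fig8_data, CONFIG,
            fallback_set=frozenset({"C1", "C2"}),
        )
        assert ev.no_sufficient_set
        assert any("no sufficient" in note for note in ev.consistency.notes)


@pytest.fixture(scope="module")
def priors():
    return {n: fixture(n).dag for n in ("figure_1", "figure_2", "figure_3", "figure_4")}


class TestRunWorkflow:

    def test_recovers_figure_1(self, priors, fig1_data):
        result = run_workflow(priors, "figure_2", Q, fig1_data, CONFIG)
        assert result.final_dags == ("figure_1",)
        assert result.all_consistent == ("figure_1", "figure_3")
        assert not result.unresolved
        # the two minimal sets of the final DAG agree within threshold
        (ev,) = result.final_evaluations()
        assert not ev.cross_set_inconsistent

    def test_single_true_prior_one_pass(self, fig1_data):
        result = run_workflow(
            {"figure_1": fixture("figure_1").dag}, "figure_1", Q, fig1_data, CONFIG
        )
        assert result.final_dags == ("figure_1",)

    def test_unresolved_when_only_wrong_prior(self, fig1_data):
        result = run_workflow(
            {"figure_2": fixture("figure_2").dag}, "figure_2", Q, fig1_data, CONFIG
        )
        assert result.unresolved
        assert result.final_dags == ()
        assert any("none of the prior DAGs" in line for line in result.iteration_log)

    def test_idempotent_on_final_set(self, priors, fig1_data):
        first = run_workflow(priors, "figure_2", Q, fig1_data, CONFIG)
        again = run_workflow(
            {n: priors[n] for n in first.final_dags},
            first.final_dags[0],
            Q,
            fig1_data,
            CONFIG,
        )
        assert again.final_dags == first.final_dags

    def test_working_dag_must_be_a_prior(self, priors, fig1_data):
        with pytest.raises(ValueError, match="not among"):
            run_workflow(priors, "figure_9", Q, fig1_data, CONFIG)

    def test_result_serializes(self, priors, fig1_data, tmp_path):
        import json

        result = run_workflow(priors, "figure_2", Q, fig1_data, CONFIG)
        path = tmp_path / "result.json"
        result.to_json(path)
        doc = json.loads(path.read_text())
        assert doc["final_dags"] == ["figure_1"]
        assert set(doc["evaluations"]) == set(priors)


class TestAsymmetricRule:
    """No DAG is ever rejected solely for an implied change not observed."""

    def test_property_on_random_observations(self, fig1_data):
        rng = np.random.default_rng(77)
        from dataclasses import replace

        adds = sweep_add_one(fig1_data.head(5000), Q, {"C1"}, ["C2", "C3", "C4", "C5"], rule=ABS_RULE)
        minus = sweep_minus_one(fig1_data.head(5000), Q, {"C1"}, rule=ABS_RULE)
        implied = implied_pattern(fixture("figure_3").dag, Q, {"C1"})
        for _ in range(50):
            # random observed meaningfulness patterns
            observed = [
                replace(r, meaningful=bool(rng.integers(0, 2))) for r in adds + minus
            ]
            report = check_consistency(implied, observed)
            for key, verdict in report.verdicts.items():
                var, direction = key
                mapping = implied.add_one if direction == "add" else implied.minus_one
                if mapping[var].verdict == "CHANGE":
                    assert verdict in (OK, FLAGGED_WEAK_FAITHFULNESS)
                    assert verdict != INCONSISTENT
            # figure_3 implies CHANGE everywhere at {C1}: can never be rejected
            assert report.dag_verdict == "consistent"


class TestPatternPlot:
    def test_renders_nonempty_file(self, fig1_data, tmp_path):
        adds = sweep_add_one(fig1_data.head(5000), Q, {"C1"}, ["C2"], rule=ABS_RULE)
        out = tmp_path / "pattern.png"
        render_pattern_plot(adds[0].base, adds, [ABS_RULE], out=out)
        assert out.exists() and out.stat().st_size > 0

    def test_plot_structure(self, fig1_observed_at_c1):
        import matplotlib

        matplotlib.use("Agg")
        base = fig1_observed_at_c1[0].base
        ax = render_pattern_plot(base, fig1_observed_at_c1, [ABS_RULE])
        labels = [t.get_text() for t in ax.get_xticklabels()]
        assert labels == ["+C2", "+C3", "+C4", "+C5", "-C1"]
        # base line + two threshold guides
        assert len(ax.lines) >= 3
        ax.figure.clf()

    def test_relative_guides_inside_absolute_when_base_small(self):
        import matplotlib

        matplotlib.use("Agg")
        from dagcie.estimation import EffectEstimate
        from dataclasses import replace as drep

        base = EffectEstimate("RD", -0.02, 0.005, -0.03, -0.01, 100, frozenset())
        varied = EffectEstimate("RD", -0.05, 0.005, -0.06, -0.04, 100, frozenset())
        from dagcie.estimation import _make_record

        rec = _make_record("X", "add", base, varied, ABS_RULE)
        rules = [ABS_RULE, ThresholdRule("relative", 0.10)]
        ax = render_pattern_plot(base, [rec], rules)
        guides = sorted(
            line.get_ydata()[0] for line in ax.lines if line.get_linestyle() in (":", "--")
        )
        # absolute band: -0.03, -0.01; relative band: -0.022, -0.018
        assert guides[0] == pytest.approx(-0.03)
        assert guides[-1] == pytest.approx(-0.01)
        assert guides[1] == pytest.approx(-0.022)
        assert guides[2] == pytest.approx(-0.018)
        ax.figure.clf()

    def test_empty_records_rejected(self, fig1_observed_at_c1):
        with pytest.raises(ValueError):
            render_pattern_plot(fig1_observed_at_c1[0].base, [], [ABS_RULE])
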