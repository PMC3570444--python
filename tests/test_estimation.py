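"""Collapsible RD/RR estimation and meaningful-change classification."""

import numpy as np
import pandas as pd
import pytest

from dagcie.dag_core import Query
from dagcie.estimation import (
    EstimationError,
    ModelFailure,
    ThresholdRule,
    UndefinedChangeError,
    classify_change,
    compare_minimal_sets,
    estimate_effect,
    sweep_add_one,
    sweep_minus_one,
)
from dagcie.synthetic_data import analytic_rd, fixture, population_adjusted_rd, simulate

Q = Query("A", "Y")
ABS_RULE = ThresholdRule("absolute", 0.01)


def two_by_two(p1=0.30, p0=0.20, n=1000):
    """Deterministic 2x2 data with exact group proportions."""
    rows = []
    for a, p in ((1, p1), (0, p0)):
        k = int(round(p * n))
        rows += [{"A": a, "Y": 1}] * k + [{"A": a, "Y": 0}] * (n - k)
    return pd.DataFrame(rows)


class TestClosedForms:
    def test_rd_equals_difference_of_proportions(self):
        est = estimate_effect(two_by_two(), Q)
        assert est.point == pytest.approx(0.10, abs=1e-12)
        assert est.ci_low <= est.point <= est.ci_high
        assert est.n_used == 2000

    def test_rr_equals_ratio_of_proportions(self):
        est = estimate_effect(two_by_two(), Q, estimator="RR")
        assert est.point == pytest.approx(1.5, rel=1e-9)
        assert est.ci_low <= est.point <= est.ci_high

    def test_rd_matches_sandwich_of_statsmodels_reference(self):
        # independent route: group proportions and their binomial variances
        df = two_by_two(0.4, 0.25, 500)
        est = estimate_effect(df, Q)
        p1, p0, n = 0.4, 0.25, 500
        se_ref = np.sqrt(p1 * (1 - p1) / n + p0 * (1 - p0) / n)
        assert est.se == pytest.approx(se_ref, rel=5e-3)  # HC1 vs exact binomial


class TestValidation:
    def test_non_binary_outcome_rejected(self):
        df = two_by_two()
        df.loc[0, "Y"] = 2
        with pytest.raises(EstimationError, match="coded 0/1"):
            estimate_effect(df, Q)

    def test_collinear_covariates_named(self):
        df = two_by_two()
        df["X1"] = np.tile([0, 1], len(df) // 2)
        df["X2"] = df["X1"]
        with pytest.raises(ModelFailure, match="X2"):
            estimate_effect(df, Q, {"X1", "X2"})

    def test_zero_cell_rr_fails(self):
        df = two_by_two(p1=0.3, p0=0.0)
        with pytest.raises(ModelFailure, match="zero outcome events"):
            estimate_effect(df, Q, estimator="RR")

    def test_single_exposure_level_fails(self):
        df = two_by_two()
        with pytest.raises(ModelFailure, match="single level"):
            estimate_effect(df[df["A"] == 1], Q)


class TestClassifyChange:
    def test_absolute_rule_arithmetic(self):
        assert classify_change(-0.07, -0.085, ABS_RULE)
        assert not classify_change(-0.07, -0.075, ABS_RULE)

    def test_zero_delta_never_meaningful(self):
        for rule in (ABS_RULE, ThresholdRule("relative", 0.10)):
            assert not classify_change(0.3, 0.3, rule)

    def test_relative_widths_track_base_magnitude(self):
        rel = ThresholdRule("relative", 0.10)
        # base -0.07: relative width 0.007, close to the absolute 0.01
        assert rel.width(-0.07) == pytest.approx(0.007)
        # base -0.02: relative width 0.002, much narrower than 0.01
        assert rel.width(-0.02) == pytest.approx(0.002)

    def test_boundary_is_not_meaningful(self):
        assert not classify_change(0.0, 0.01, ABS_RULE)
        assert classify_change(0.0, 0.0100001, ABS_RULE)

    def test_relative_rule_with_zero_base(self):
        with pytest.raises(UndefinedChangeError):
            classify_change(0.0, 0.05, ThresholdRule("relative", 0.10))

    def test_invalid_rules(self):
        with pytest.raises(EstimationError):
            ThresholdRule("percent", 0.1)
        with pytest.raises(EstimationError):
            ThresholdRule("absolute", 0.0)


class TestOnSimulatedData:
    def test_adjusted_rd_converges_to_analytic_value(self, fig1, fig1_data):
        truth = analytic_rd(fig1.sem, fig1.dag, Q)
        for s in ({"C1", "C2"}, {"C1", "C3"}):
            est = estimate_effect(fig1_data, Q, s)
            assert abs(est.point - truth) < 3 * est.se

    def test_collapsibility_of_sufficient_sets(self, fig1_data):
        est_a = estimate_effect(fig1_data, Q, {"C1", "C2"})
        est_b = estimate_effect(fig1_data, Q, {"C1", "C3"})
        assert abs(est_a.point - est_b.point) < 0.01

    def test_estimate_invariant_to_adjustment_order(self, fig1_data):
        a = estimate_effect(fig1_data, Q, ["C1", "C2"])
        b = estimate_effect(fig1_data, Q, ["C2", "C1"])
        assert a.point == b.point and a.se == b.se

    def test_ci_shrinks_with_n(self, fig1_data):
        small = estimate_effect(fig1_data.head(10_000), Q, {"C1", "C2"})
        large = estimate_effect(fig1_data, Q, {"C1", "C2"})
        ratio = (small.ci_high - small.ci_low) / (large.ci_high - large.ci_low)
        assert ratio == pytest.approx(np.sqrt(10), rel=0.15)

    def test_complete_case_count(self, fig1_data):
        df = fig1_data.head(1000).copy()
        df.loc[:49, "C1"] = np.nan
        est = estimate_effect(df, Q, {"C1"})
        assert est.n_used == 950


class TestSweeps:
    def test_empty_inputs(self, fig1_data):
        assert sweep_add_one(fig1_data, Q, {"C1"}, [], rule=ABS_RULE) == []
        assert sweep_minus_one(fig1_data, Q, set(), rule=ABS_RULE) == []

    def test_figure_1_add_one_from_c1(self, fig1_data):
        records = sweep_add_one(
            fig1_data, Q, {"C1"}, ["C2", "C3", "C4", "C5"], rule=ABS_RULE
        )
        assert {r.variable: r.meaningful for r in records} == {
            "C2": True, "C3": True, "C4": True, "C5": True
        }

    def test_pure_noise_column_not_meaningful(self, fig1_data):
        df = fig1_data.copy()
        df["noise"] = np.random.default_rng(99).integers(0, 2, len(df))
        (rec,) = sweep_add_one(df, Q, {"C1", "C2"}, ["noise"], rule=ABS_RULE)
        assert not rec.meaningful
        assert rec.delta_abs < 0.005

    def test_figure_1_minus_one_patterns(self, fig1, fig1_data):
        recs = sweep_minus_one(fig1_data, Q, {"C1", "C2"}, rule=ABS_RULE)
        assert {r.variable: r.meaningful for r in recs} == {"C1": True, "C2": True}
        recs = sweep_minus_one(fig1_data, Q, {"C1", "C2", "C3"}, rule=ABS_RULE)
        assert {r.variable: r.meaningful for r in recs} == {
            "C1": True, "C2": False, "C3": False
        }

    def test_overlapping_candidates_rejected(self, fig1_data):
        with pytest.raises(EstimationError, match="overlap"):
            sweep_add_one(fig1_data, Q, {"C1"}, ["C1", "C2"], rule=ABS_RULE)

    def test_failed_fit_yields_unusable_record(self, fig1_data):
        df = fig1_data.head(2000).copy()
        df["dup"] = df["C2"]
        records = sweep_add_one(df, Q, {"C1", "C2"}, ["dup", "C3"], rule=ABS_RULE)
        by_var = {r.variable: r for r in records}
        assert not by_var["dup"].usable and "fit failed" in by_var["dup"].note
        assert by_var["C3"].usable  # the sweep continued


class TestCompareMinimalSets:
    def test_single_set_empty_result(self, fig1_data):
        assert compare_minimal_sets(fig1_data, Q, [{"C1", "C2"}]) == []

    def test_figure_1_sets_agree(self, fig1_data):
        (rec,) = compare_minimal_sets(
            fig1_data, Q, [{"C1", "C2"}, {"C1", "C3"}], rule=ABS_RULE
        )
        assert not rec.meaningful

    def test_figure_8_sets_disagree(self, fig8_data):
        (rec,) = compare_minimal_sets(
            fig8_data, Q, [{"C1", "C2"}, {"C1", "C3"}], rule=ABS_RULE
        )
        assert rec.meaningful
        assert rec.delta_abs > 0.01


def test_population_oracle_matches_estimator(fig1, fig1_data):
    """The exact population coefficient and the finite-sample fit agree."""
    for s in (set(), {"C1"}, {"C1", "C2"}):
        exact = population_adjusted_rd(fig1.sem, fig1.dag, Q, s)
        est = estimate_effect(fig1_data, Q, s)
        assert abs(est.point - exact) < 4 * est.se
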