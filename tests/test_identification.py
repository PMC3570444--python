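"""Path blocking, d-separation, sufficiency, minimal sets, c-equivalence."""

import itertools

import numpy as np
import pytest

from dagcie.dag_core import Dag, DagError, Node, Query, parse_dag
from dagcie.identification import (
    MAX_CANDIDATE_POOL,
    c_equivalence,
    candidate_pool,
    d_separated,
    is_sufficient,
    minimal_sufficient_sets,
    proper_paths,
)
from dagcie.synthetic_data import fixture

from .conftest import (
    mid_query,
    oracle_d_separated,
    oracle_minimal_sufficient_sets,
    random_dag,
)

Q = Query("A", "Y")


class TestProperPaths:
    def test_collider_blocked_unconditioned(self):
        dag = parse_dag("A -> B\nC -> B\nC -> Y\nA -> Y")
        reports = {r.nodes: r for r in proper_paths(dag, Q)}
        collider_path = reports[("A", "B", "C", "Y")]
        assert collider_path.status == "blocked"
        assert collider_path.blockers == ("B",)
        assert collider_path.klass == "noncausal"

    def test_figure_1_backdoor_open_given_c1(self, fig1):
        reports = {r.nodes: r for r in proper_paths(fig1.dag, Q, {"C1"})}
        path = reports[("A", "C2", "C3", "Y")]
        assert path.status == "open" and path.klass == "noncausal"

    def test_figure_6_partial_block_at_latent(self):
        dag = fixture("figure_6").dag
        reports = {r.nodes: r for r in proper_paths(dag, Q, {"C1", "C2*"})}
        path = reports[("A", "C2", "C3", "Y")]
        assert path.status == "partially_blocked"
        assert path.blockers == ("C2",)

    def test_each_path_reported_once(self, fig1):
        reports = proper_paths(fig1.dag, Q)
        keys = [r.nodes for r in reports]
        assert len(keys) == len(set(keys))

    def test_conditioning_on_exposure_rejected(self, fig1):
        with pytest.raises(DagError, match="exposure or outcome"):
            proper_paths(fig1.dag, Q, {"A"})

    def test_selection_opens_collider(self):
        dag = parse_dag(
            "node S kind=selection\nA -> S\nC -> S\nC -> Y\nA -> Y"
        )
        reports = {r.nodes: r for r in proper_paths(dag, Query("A", "Y"))}
        assert reports[("A", "S", "C", "Y")].status == "open"


class TestDSeparation:
    def test_chain_and_collider(self):
        chain = parse_dag("X -> Z\nZ -> Y")
        assert d_separated(chain, "X", "Y", {"Z"})
        assert not d_separated(chain, "X", "Y", set())
        collider = parse_dag("X -> Z\nY -> Z")
        assert d_separated(collider, "X", "Y", set())
        assert not d_separated(collider, "X", "Y", {"Z"})

    def test_figure_1_not_separated_given_c1(self, fig1):
        assert not d_separated(fig1.dag, "A", "Y", {"C1"})

    def test_proxy_conditioning_does_not_separate(self):
        dag = fixture("figure_6").dag
        # conditioning the proxies leaves the latent path open
        assert not d_separated(dag, "C2", "Y", {"C2*", "C3*", "C1", "A"})

    def test_oracle_agreement_random_dags(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            dag = random_dag(rng)
            names = list(dag.node_names)
            for x, y in itertools.combinations(names, 2):
                rest = [n for n in names if n not in (x, y)]
                sets = [frozenset()] + [frozenset([r]) for r in rest]
                for _ in range(4):
                    k = int(rng.integers(2, 4))
                    if len(rest) >= k:
                        sets.append(frozenset(rng.choice(rest, size=k, replace=False)))
                for s in set(sets):
                    assert d_separated(dag, x, y, s) == oracle_d_separated(dag, x, y, s)


class TestSufficiency:
    @pytest.mark.parametrize(
        "name,s,expected",
        [
            ("figure_1", {"C1", "C2"}, True),
            ("figure_1", {"C1", "C3"}, True),
            ("figure_1", {"C1"}, False),
            ("figure_2", {"C1"}, True),
            ("figure_6", {"C1", "C2*", "C3*"}, False),  # partial blocking only
            ("figure_9", {"Age", "Comorbidity index"}, True),
        ],
    )
    def test_quoted_sufficiency(self, name, s, expected):
        entry = fixture(name)
        assert is_sufficient(entry.dag, entry.query, s) is expected

    def test_figure_12_no_measured_subset_sufficient(self):
        entry = fixture("figure_12")
        pool = candidate_pool(entry.dag, entry.query)
        for size in range(len(pool) + 1):
            for combo in itertools.combinations(pool, size):
                assert not is_sufficient(entry.dag, entry.query, frozenset(combo))

    def test_descendant_in_set_is_an_error_not_false(self, fig1):
        with pytest.raises(DagError, match="descends"):
            is_sufficient(fig1.dag, Q, {"C1", "C4"})

    def test_latent_in_set_is_an_error(self):
        dag = fixture("figure_8").dag
        with pytest.raises(DagError, match="latent"):
            is_sufficient(dag, Q, {"ZU"})


class TestMinimalSets:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("figure_1", [{"C1", "C2"}, {"C1", "C3"}]),
            ("figure_2", [{"C1"}]),
            ("figure_3", [{"C1", "C2", "C3"}]),
            ("figure_9", [{"Age", "Comorbidity index"}]),
            ("figure_8", []),
            ("figure_12", []),
        ],
    )
    def test_quoted_minimal_sets(self, name, expected):
        entry = fixture(name)
        assert minimal_sufficient_sets(entry.dag, entry.query) == [
            frozenset(s) for s in expected
        ]

    def test_oracle_agreement_random_dags(self):
        rng = np.random.default_rng(7)
        for _ in range(120):
            dag = random_dag(rng)
            q = mid_query(dag)
            assert minimal_sufficient_sets(dag, q) == oracle_minimal_sufficient_sets(dag, q)

    def test_returned_sets_are_minimal_and_sufficient(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            dag = random_dag(rng)
            q = mid_query(dag)
            for s in minimal_sufficient_sets(dag, q):
                assert is_sufficient(dag, q, s)
                for v in s:
                    assert not is_sufficient(dag, q, s - {v})

    def test_pool_guard(self):
        nodes = [Node("A"), Node("Y")] + [Node(f"C{i:02d}") for i in range(22)]
        edges = [("A", "Y")] + [(f"C{i:02d}", "A") for i in range(22)] + [
            (f"C{i:02d}", "Y") for i in range(22)
        ]
        dag = Dag(nodes, edges)
        with pytest.raises(DagError, match=str(MAX_CANDIDATE_POOL)):
            minimal_sufficient_sets(dag, Q)


class TestCEquivalence:
    def test_figure_1_sufficient_sets_equivalent(self, fig1):
        assert c_equivalence(fig1.dag, Q, {"C1", "C2"}, {"C1", "C3"}) == "equivalent"

    def test_figure_8_amplification(self):
        dag = fixture("figure_8").dag
        assert (
            c_equivalence(dag, Q, {"C1", "C2"}, {"C1", "C3"})
            == "not_equivalent_amplification"
        )

    def test_self_equivalence(self, fig1):
        for s in ({"C1"}, {"C1", "C2"}, set()):
            assert c_equivalence(fig1.dag, Q, s, s) == "equivalent"

    def test_different_open_paths_not_equivalent(self, fig1):
        # {C1} leaves the C2 backdoor open; {C1,C2} closes it
        assert c_equivalence(fig1.dag, Q, {"C1"}, {"C1", "C2"}) == "not_equivalent"

    def test_all_minimal_set_pairs_equivalent_without_latents(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            dag = random_dag(rng)
            q = mid_query(dag)
            msets = minimal_sufficient_sets(dag, q)
            for s, t in itertools.combinations(msets, 2):
                assert c_equivalence(dag, q, s, t) == "equivalent"
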