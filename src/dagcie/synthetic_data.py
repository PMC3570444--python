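"""Structural-equation simulation over annotated DAGs, with exact oracles.

Each node carries a mechanism, linear in its parents:

``bernoulli_linear``
    a binary variable drawn with success probability
    ``intercept + sum(coef[p] * parent_p)``.  Linearity *in probability*
    makes the risk difference collapsible and exactly computable by path
    tracing, so every graph-side prediction has an analytic counterpart.
``gaussian_linear``
    a continuous covariate ``intercept + sum(coef[p] * parent_p) + noise``.

Proxy nodes (measured stand-ins for latent variables) may instead carry a
single misclassification probability: the proxy equals its latent target
flipped independently with that probability, i.e. a ``bernoulli_linear``
mechanism with intercept ``eps`` and slope ``1 - 2*eps``.

Simulation draws rows in topological order, filters on selection nodes
(only rows with every selection variable equal to 1 are emitted, mimicking
registry inclusion), and drops latent columns from the emitted dataset.

Two exact oracles are provided for testing and calibration:

* :func:`analytic_rd` — the interventional risk difference by path tracing
  (sum over directed exposure-outcome paths of the product of edge
  coefficients);
* :func:`population_adjusted_rd` — the exact population least-squares
  exposure coefficient for any adjustment set, computed on the selected
  population by exhaustive enumeration of the binary joint distribution.
  This is what the linear-probability estimator converges to, including
  any residual confounding, selection, proxy, or amplification bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as iter_product

import numpy as np
import pandas as pd

from .dag_core import Dag, Node, Query

__all__ = [
    "Mechanism",
    "SemSpec",
    "SemError",
    "simulate",
    "analytic_rd",
    "interventional_rd",
    "population_table",
    "population_adjusted_rd",
    "FixtureEntry",
    "fixture",
    "fixture_names",
]

FAMILIES = ("bernoulli_linear", "gaussian_linear")

PROB_FLOOR = 0.01
PROB_CEIL = 0.99


class SemError(ValueError):
    """Invalid structural-equation specification."""


@dataclass(frozen=True)
class Mechanism:
    """Linear mechanism for one node."""

    family: str
    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SemError(f"unknown mechanism family {self.family!r}")
        if any(c == 0 for c in self.coefficients.values()):
            raise SemError("zero coefficients are not allowed (faithfulness)")
        if self.family == "bernoulli_linear" and self.noise_sd:
            raise SemError("noise_sd applies to gaussian_linear only")


@dataclass(frozen=True)
class SemSpec:
    """Structural-equation model attached to a :class:`~dagcie.dag_core.Dag`.

    ``mechanisms`` maps node name to :class:`Mechanism`; a proxy node may
    instead appear in ``proxy_noise`` (flip probability).  ``seed`` is the
    default random seed for :func:`simulate`.
    """

    mechanisms: dict[str, Mechanism]
    proxy_noise: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def mechanism_for(self, dag: Dag, name: str) -> Mechanism:
        if name in self.mechanisms:
            return self.mechanisms[name]
        if name in self.proxy_noise:
            eps = self.proxy_noise[name]
            target = dag.node(name).proxy_of
            return Mechanism("bernoulli_linear", eps, {target: 1.0 - 2.0 * eps})
        raise SemError(f"no mechanism for node {name!r}")

    def validate(self, dag: Dag) -> None:
        """Check mechanism/DAG agreement and probability bounds.

        For ``bernoulli_linear`` nodes the reachable success probability is
        bounded by interval arithmetic over parent supports ({0,1} for
        binary parents, mean +/- 4 sd for gaussian parents) and must stay
        within (0.01, 0.99).
        """
        for name in dag.node_names:
            node = dag.node(name)
            if name in self.proxy_noise:
                if node.proxy_of is None:
                    raise SemError(f"proxy_noise given for non-proxy node {name!r}")
                eps = self.proxy_noise[name]
                if not 0 < eps < 0.5:
                    raise SemError(f"proxy_noise for {name!r} must be in (0, 0.5)")
                if set(dag.parents(name)) != {node.proxy_of}:
                    raise SemError(
                        f"proxy shortcut for {name!r} requires its latent target "
                        "as sole parent; give a full mechanism otherwise"
                    )
                if name in self.mechanisms:
                    raise SemError(f"node {name!r} has both mechanism and proxy_noise")
                continue
            mech = self.mechanism_for(dag, name)
            if set(mech.coefficients) != set(dag.parents(name)):
                raise SemError(
                    f"mechanism for {name!r} must have coefficients for exactly "
                    f"its parents {sorted(dag.parents(name))}, got "
                    f"{sorted(mech.coefficients)}"
                )
            if mech.family == "bernoulli_linear":
                lo, hi = self._prob_bounds(dag, name, mech)
                if lo < PROB_FLOOR or hi > PROB_CEIL:
                    raise SemError(
                        f"bernoulli_linear probability for {name!r} can reach "
                        f"[{lo:.3f}, {hi:.3f}], outside ({PROB_FLOOR}, {PROB_CEIL})"
                    )

    def _parent_support(self, dag: Dag, parent: str) -> tuple[float, float]:
        mech = self.mechanism_for(dag, parent)
        if mech.family == "bernoulli_linear":
            return 0.0, 1.0
        lo = mech.intercept
        hi = mech.intercept
        for p, c in mech.coefficients.items():
            plo, phi = self._parent_support(dag, p)
            lo += min(c * plo, c * phi)
            hi += max(c * plo, c * phi)
        return lo - 4.0 * mech.noise_sd, hi + 4.0 * mech.noise_sd

    def _prob_bounds(self, dag: Dag, name: str, mech: Mechanism) -> tuple[float, float]:
        lo = hi = mech.intercept
        for p, c in mech.coefficients.items():
            plo, phi = self._parent_support(dag, p)
            lo += min(c * plo, c * phi)
            hi += max(c * plo, c * phi)
        return lo, hi

    def is_all_binary(self, dag: Dag) -> bool:
        return all(
            self.mechanism_for(dag, n).family == "bernoulli_linear"
            for n in dag.node_names
        )


# ---------------------------------------------------------------------------
# simulation


def simulate(
    dag: Dag,
    sem: SemSpec,
    n: int,
    seed: int | None = None,
    include_latent: bool = False,
) -> pd.DataFrame:
    """Draw ``n`` subjects, filter on selection, drop latent columns.

    Deterministic given ``seed`` (defaults to ``sem.seed``).  The returned
    frame's ``attrs`` carry ``n_requested`` (pre-filter) and ``n_emitted``.
    With ``include_latent=True`` the latent columns are retained (oracle
    output for debugging; never feed them to the estimator).
    """
    if n < 1:
        raise SemError("n must be >= 1")
    sem.validate(dag)
    rng = np.random.default_rng(sem.seed if seed is None else seed)

    columns: dict[str, np.ndarray] = {}
    for name in dag.topological_order():
        mech = sem.mechanism_for(dag, name)
        value = np.full(n, mech.intercept, dtype=float)
        for parent, coef in mech.coefficients.items():
            value += coef * columns[parent]
        if mech.family == "bernoulli_linear":
            if value.min() < 0 or value.max() > 1:  # pragma: no cover - guarded
                raise SemError(f"probability out of [0,1] for {name!r}")
            columns[name] = (rng.random(n) < value).astype(float)
        else:
            columns[name] = value + mech.noise_sd * rng.standard_normal(n)

    df = pd.DataFrame({k: columns[k] for k in sorted(columns)})
    for sel in sorted(dag.selection_nodes()):
        df = df[df[sel] == 1.0]
    if not include_latent:
        df = df.drop(columns=sorted(dag.latent_nodes()))
    df = df.reset_index(drop=True)
    df.attrs["n_requested"] = n
    df.attrs["n_emitted"] = len(df)
    return df


# ---------------------------------------------------------------------------
# exact oracles


def analytic_rd(sem: SemSpec, dag: Dag, query: Query) -> float:
    """Interventional risk difference by path tracing.

    With every mechanism linear, ``E[Y | do(A=1)] - E[Y | do(A=0)]`` equals
    the sum over directed exposure-to-outcome paths of the product of edge
    coefficients.  This is the total effect in the *unselected* source
    population.
    """
    import networkx as nx

    query.validate(dag)
    for name in dag.node_names:
        mech = sem.mechanism_for(dag, name)
        if mech.family not in FAMILIES:  # pragma: no cover - future families
            raise SemError(f"non-linear mechanism on {name!r}")
    g = nx.DiGraph(dag.edges)
    total = 0.0
    if query.outcome in g and query.exposure in g:
        for path in nx.all_simple_paths(g, query.exposure, query.outcome):
            prod = 1.0
            for tail, head in zip(path, path[1:]):
                prod *= sem.mechanism_for(dag, head).coefficients[tail]
            total += prod
    return total


def population_table(sem: SemSpec, dag: Dag) -> pd.DataFrame:
    """Exact joint distribution over all-binary configurations.

    One row per configuration of every node (latent and selection included)
    with its probability in column ``_prob``.  Requires an all-binary SEM.
    """
    if not sem.is_all_binary(dag):
        raise SemError("population_table requires an all-binary SEM")
    sem.validate(dag)
    order = dag.topological_order()
    configs = list(iter_product((0.0, 1.0), repeat=len(order)))
    table = pd.DataFrame(configs, columns=list(order))
    prob = np.ones(len(table))
    for name in order:
        mech = sem.mechanism_for(dag, name)
        p = np.full(len(table), mech.intercept)
        for parent, coef in mech.coefficients.items():
            p += coef * table[parent].to_numpy()
        x = table[name].to_numpy()
        prob *= np.where(x == 1.0, p, 1.0 - p)
    table = table[sorted(order)]
    table["_prob"] = prob
    return table


def interventional_rd(sem: SemSpec, dag: Dag, query: Query) -> float:
    """``E[Y|do(A=1)] - E[Y|do(A=0)]`` by exhaustive enumeration.

    Independent cross-check of :func:`analytic_rd`: the exposure mechanism
    is replaced by a point mass and the outcome mean computed exactly.
    """
    means = []
    for a in (0.0, 1.0):
        forced = SemSpec(
            mechanisms={
                **{k: m for k, m in sem.mechanisms.items() if k != query.exposure},
                query.exposure: Mechanism(
                    "bernoulli_linear",
                    max(PROB_FLOOR, min(PROB_CEIL, a)),
                    {},
                ),
            },
            proxy_noise=dict(sem.proxy_noise),
        )
        cut = dag.with_edges_removed(
            [(p, query.exposure) for p in dag.parents(query.exposure)]
        )
        table = population_table(forced, cut)
        # point mass at a, up to the probability floor/ceiling guard
        w = table["_prob"].to_numpy()
        y = table[query.outcome].to_numpy()
        x = table[query.exposure].to_numpy()
        keep = x == a
        means.append(float((w[keep] * y[keep]).sum() / w[keep].sum()))
    return means[1] - means[0]


def population_adjusted_rd(
    sem: SemSpec,
    dag: Dag,
    query: Query,
    adjustment=(),
) -> float:
    """Exact population linear-probability coefficient of the exposure.

    Weighted least squares of the outcome on the exposure plus the
    adjustment columns over the exact joint distribution of the *selected*
    population (all selection nodes conditioned to 1).  This is the
    estimand the finite-sample linear-probability estimator converges to.
    """
    table = population_table(sem, dag)
    for sel in sorted(dag.selection_nodes()):
        table = table[table[sel] == 1.0]
    w = table["_prob"].to_numpy()
    w = w / w.sum()
    cols = [query.exposure, *sorted(set(adjustment))]
    X = np.column_stack(
        [np.ones(len(table))] + [table[c].to_numpy() for c in cols]
    )
    y = table[query.outcome].to_numpy()
    WX = X * w[:, None]
    beta = np.linalg.solve(X.T @ WX, WX.T @ y)
    return float(beta[1])


# ---------------------------------------------------------------------------
# fixture library
#
# Canonical reconstructions of the worked examples: a confounding/mediation
# graph and variants (figures 1-4), its measurement-error version (figure
# 6), a residual-confounding version (figure 8), and the registry example
# with a selection node (figure 9) and its latent-proxy variant (figure
# 12).  Coefficients are committed so that every graph-implied CHANGE
# corresponds to an analytic adjusted-RD delta above 0.02 (double the
# default 0.01 threshold) and every implied NO_CHANGE delta is exactly 0.


@dataclass(frozen=True)
class FixtureEntry:
    """A named DAG + SEM with the textual constraints it must satisfy."""

    name: str
    dag: Dag
    sem: SemSpec
    query: Query
    constraints: tuple[str, ...]

    def verify(self) -> None:
        """Re-derive every constraint; raises AssertionError on failure."""
        _verify_fixture(self)


def _bern(p: float) -> Mechanism:
    return Mechanism("bernoulli_linear", p)


def _lin(intercept: float, **coefs: float) -> Mechanism:
    return Mechanism("bernoulli_linear", intercept, dict(coefs))


def _figure_1() -> tuple[Dag, SemSpec]:
    dag = Dag(
        nodes=[Node(n) for n in ("A", "Y", "C1", "C2", "C3", "C4", "C5")],
        edges=[
            ("C1", "A"), ("C1", "Y"),
            ("C2", "A"), ("C2", "C3"), ("C3", "Y"),
            ("A", "C4"), ("C4", "Y"),
            ("A", "C5"), ("C5", "Y"),
            ("A", "Y"),
        ],
    )
    sem = SemSpec(
        mechanisms={
            "C1": _bern(0.5),
            "C2": _bern(0.5),
            "C3": _lin(0.15, C2=0.55),
            "A": _lin(0.15, C1=0.25, C2=0.35),
            "C4": _lin(0.20, A=0.40),
            "C5": _lin(0.20, A=0.40),
            "Y": _lin(0.04, A=0.12, C1=0.18, C3=0.25, C4=0.12, C5=0.12),
        }
    )
    return dag, sem


def _figure_2() -> tuple[Dag, SemSpec]:
    dag = Dag(
        nodes=[Node(n) for n in ("A", "Y", "C1", "C2", "C3", "C4", "C5")],
        edges=[
            ("C1", "A"), ("C1", "Y"),
            ("C2", "A"), ("C3", "Y"),
            ("A", "C4"), ("C4", "Y"),
            ("A", "C5"), ("C5", "Y"),
            ("A", "Y"),
        ],
    )
    sem = SemSpec(
        mechanisms={
            "C1": _bern(0.5),
            "C2": _bern(0.5),
            "C3": _bern(0.5),
            "A": _lin(0.15, C1=0.25, C2=0.35),
            "C4": _lin(0.20, A=0.40),
            "C5": _lin(0.20, A=0.40),
            "Y": _lin(0.04, A=0.12, C1=0.18, C3=0.25, C4=0.12, C5=0.12),
        }
    )
    return dag, sem


def _figure_3() -> tuple[Dag, SemSpec]:
    dag = Dag(
        nodes=[Node(n) for n in ("A", "Y", "C1", "C2", "C3", "C4", "C5")],
        edges=[
            ("C1", "A"), ("C1", "Y"),
            ("C2", "A"), ("C2", "Y"),
            ("C3", "A"), ("C3", "Y"),
            ("A", "C4"), ("C4", "Y"),
            ("A", "C5"), ("C5", "Y"),
            ("A", "Y"),
        ],
    )
    sem = SemSpec(
        mechanisms={
            "C1": _bern(0.5),
            "C2": _bern(0.5),
            "C3": _bern(0.5),
            "A": _lin(0.10, C1=0.20, C2=0.25, C3=0.25),
            "C4": _lin(0.20, A=0.40),
            "C5": _lin(0.20, A=0.40),
            "Y": _lin(0.04, A=0.12, C1=0.15, C2=0.18, C3=0.18, C4=0.12, C5=0.12),
        }
    )
    return dag, sem


def _figure_4() -> tuple[Dag, SemSpec]:
    # C2 is a collider here (A -> C2 <- Y, with parent C3): adding C2 to
    # {C1} opens the collider path, while adding the collider's parent C3
    # opens nothing, so the pattern is change for C2/C4/C5 and no change
    # for C3 — distinguishable from the confounding variants at {C1}.
    dag = Dag(
        nodes=[Node(n) for n in ("A", "Y", "C1", "C2", "C3", "C4", "C5")],
        edges=[
            ("C1", "A"), ("C1", "Y"),
            ("A", "C2"), ("Y", "C2"),
            ("C3", "C2"),
            ("A", "C4"), ("C4", "Y"),
            ("A", "C5"), ("C5", "Y"),
            ("A", "Y"),
        ],
    )
    sem = SemSpec(
        mechanisms={
            "C1": _bern(0.5),
            "C3": _bern(0.5),
            "C2": _lin(0.10, A=0.30, Y=0.30, C3=0.25),
            "A": _lin(0.15, C1=0.35),
            "C4": _lin(0.20, A=0.40),
            "C5": _lin(0.20, A=0.40),
            "Y": _lin(0.06, A=0.14, C1=0.22, C4=0.14, C5=0.14),
        }
    )
    return dag, sem


def _figure_6() -> tuple[Dag, SemSpec]:
    base_dag, _ = _figure_1()
    dag = Dag(
        nodes=[
            Node("A"), Node("Y"), Node("C1"),
            Node("C2", "latent"), Node("C3", "latent"),
            Node("C2*", proxy_of="C2"), Node("C3*", proxy_of="C3"),
            Node("C4"), Node("C5"),
        ],
        edges=[*base_dag.edges, ("C2", "C2*"), ("C3", "C3*")],
    )
    # a stronger C2 backdoor than figure_1 so that the residual bias left
    # by proxy conditioning is well above the 0.01 change threshold
    sem = SemSpec(
        mechanisms={
            "C1": _bern(0.5),
            "C2": _bern(0.5),
            "C3": _lin(0.12, C2=0.65),
            "A": _lin(0.10, C1=0.22, C2=0.45),
            "C4": _lin(0.20, A=0.40),
            "C5": _lin(0.20, A=0.40),
            "Y": _lin(0.03, A=0.12, C1=0.15, C3=0.32, C4=0.12, C5=0.12),
        },
        proxy_noise={"C2*": 0.10, "C3*": 0.10},
    )
    return dag, sem


def _figure_8() -> tuple[Dag, SemSpec]:
    base_dag, _ = _figure_1()
    dag = Dag(
        nodes=[*(Node(n) for n in ("A", "Y", "C1", "C2", "C3", "C4", "C5")),
               Node("ZU", "latent")],
        edges=[*base_dag.edges, ("ZU", "A"), ("ZU", "Y")],
    )
    sem = SemSpec(
        mechanisms={
            "C1": _bern(0.5),
            "C2": _bern(0.5),
            "ZU": _bern(0.5),
            "C3": _lin(0.15, C2=0.45),
            "A": _lin(0.03, C1=0.12, C2=0.40, ZU=0.40),
            "C4": _lin(0.20, A=0.40),
            "C5": _lin(0.20, A=0.40),
            "Y": _lin(0.02, A=0.10, C1=0.10, C3=0.18, C4=0.10, C5=0.10, ZU=0.35),
        }
    )
    return dag, sem


def _figure_9() -> tuple[Dag, SemSpec]:
    dag = Dag(
        nodes=[
            Node("PKD"), Node("Death"), Node("Age"), Node("Sex"),
            Node("Comorbidity index"), Node("Type of assistance"),
            Node("Type of peritoneal dialysis"),
            Node("PD vs HD", "selection"),
        ],
        edges=[
            ("Age", "PKD"), ("Age", "Death"), ("Age", "Comorbidity index"),
            ("Comorbidity index", "Death"),
            ("Comorbidity index", "Type of assistance"),
            ("Age", "Type of assistance"), ("Sex", "Type of assistance"),
            ("Type of assistance", "Death"),
            ("PKD", "Type of peritoneal dialysis"),
            ("Comorbidity index", "Type of peritoneal dialysis"),
            ("PKD", "PD vs HD"), ("Comorbidity index", "PD vs HD"),
        ],
    )
    sem = SemSpec(
        mechanisms={
            "Age": _bern(0.5),
            "Sex": _bern(0.5),
            "PKD": _lin(0.15, **{"Age": 0.35}),
            "Comorbidity index": _lin(0.25, **{"Age": 0.20}),
            "Type of assistance": _lin(
                0.10, **{"Age": 0.22, "Comorbidity index": 0.28, "Sex": 0.20}
            ),
            "Type of peritoneal dialysis": _lin(
                0.20, **{"PKD": 0.30, "Comorbidity index": 0.30}
            ),
            "PD vs HD": _lin(0.28, **{"PKD": 0.35, "Comorbidity index": 0.35}),
            "Death": _lin(
                0.04,
                **{"Age": 0.33, "Comorbidity index": 0.36, "Type of assistance": 0.22},
            ),
        }
    )
    return dag, sem


def _figure_12() -> tuple[Dag, SemSpec]:
    dag = Dag(
        nodes=[
            Node("PKD"), Node("Death"), Node("Age"), Node("Sex"),
            Node("MCI", "latent"), Node("Frailty", "latent"),
            Node("Comorbidity index", proxy_of="MCI"),
            Node("Type of assistance", proxy_of="Frailty"),
            Node("Type of peritoneal dialysis"),
            Node("PD vs HD", "selection"),
        ],
        edges=[
            ("Age", "PKD"), ("Age", "Death"),
            ("Age", "Type of assistance"), ("Sex", "Type of assistance"),
            ("MCI", "PKD"), ("MCI", "Death"), ("MCI", "Frailty"),
            ("MCI", "PD vs HD"), ("MCI", "Comorbidity index"),
            ("Frailty", "Death"), ("Frailty", "PD vs HD"),
            ("Frailty", "Type of assistance"),
            ("Frailty", "Type of peritoneal dialysis"),
            ("PKD", "Type of peritoneal dialysis"),
            ("PKD", "PD vs HD"),
        ],
    )
    sem = SemSpec(
        mechanisms={
            "Age": _bern(0.5),
            "Sex": _bern(0.5),
            "MCI": _bern(0.5),
            "Frailty": _lin(0.20, **{"MCI": 0.40}),
            "PKD": _lin(0.15, **{"Age": 0.20, "MCI": 0.30}),
            "Type of assistance": _lin(
                0.08, **{"Age": 0.20, "Sex": 0.15, "Frailty": 0.40}
            ),
            "Type of peritoneal dialysis": _lin(
                0.15, **{"PKD": 0.30, "Frailty": 0.30}
            ),
            "PD vs HD": _lin(0.30, **{"PKD": 0.20, "MCI": 0.20, "Frailty": 0.20}),
            "Death": _lin(0.05, **{"Age": 0.25, "MCI": 0.25, "Frailty": 0.25}),
        },
        proxy_noise={"Comorbidity index": 0.10},
    )
    return dag, sem


_BUILDERS = {
    "figure_1": _figure_1,
    "figure_2": _figure_2,
    "figure_3": _figure_3,
    "figure_4": _figure_4,
    "figure_6": _figure_6,
    "figure_8": _figure_8,
    "figure_9": _figure_9,
    "figure_12": _figure_12,
}

_QUERIES = {
    "figure_9": Query("PKD", "Death"),
    "figure_12": Query("PKD", "Death"),
}

_CONSTRAINTS: dict[str, tuple[str, ...]] = {
    "figure_1": (
        "minimal sufficient sets are {C1,C2} and {C1,C3}",
        "the backdoor path A<-C2->C3->Y exists",
    ),
    "figure_2": (
        "minimal sufficient set is {C1}",
        "implied add-one at {C1}: change C4, C5; no change C2, C3",
        "implied minus-one at {C1}: change C1",
    ),
    "figure_3": ("minimal sufficient set is {C1,C2,C3}",),
    "figure_4": (
        "implied add-one at {C1}: change C2, C4, C5; no change C3",
        "implied minus-one at {C1}: change C1",
    ),
    "figure_6": (
        "adjusting on C2* only partially blocks A<-C2->C3->Y at C2",
        "{C1,C2*,C3*} is not sufficient (partial blocking)",
    ),
    "figure_8": (
        "no fully sufficient set of measured variables (ZU path open)",
        "the residual path A<-ZU->Y exists",
    ),
    "figure_9": (
        "minimal sufficient set is {Age, Comorbidity index}",
        "exposure and comorbidity both parent the selection node",
        "Sex and type of PD have no edge into Death",
    ),
    "figure_12": (
        "no sufficient adjustment set of measured variables",
        "the four residual paths through MCI/Frailty are present",
    ),
}

_CACHE: dict[str, FixtureEntry] = {}


def fixture_names() -> tuple[str, ...]:
    return tuple(sorted(_BUILDERS))


def fixture(name: str) -> FixtureEntry:
    """Return a canonical fixture, verifying its constraints on first load."""
    if name not in _BUILDERS:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        )
    if name not in _CACHE:
        dag, sem = _BUILDERS[name]()
        sem.validate(dag)
        entry = FixtureEntry(
            name=name,
            dag=dag,
            sem=sem,
            query=_QUERIES.get(name, Query("A", "Y")),
            constraints=_CONSTRAINTS[name],
        )
        entry.verify()
        _CACHE[name] = entry
    return _CACHE[name]


def _verify_fixture(entry: FixtureEntry) -> None:
    # local import: identification depends only on dag_core, no cycle at
    # runtime, but keep module import light
    from . import identification as ident
    from . import implied_patterns as imp

    dag, q = entry.dag, entry.query
    msets = ident.minimal_sufficient_sets(dag, q)
    name = entry.name

    def check(cond: bool, what: str) -> None:
        if not cond:
            raise AssertionError(f"fixture {name!r} violates constraint: {what}")

    if name == "figure_1":
        check(
            msets == [frozenset({"C1", "C2"}), frozenset({"C1", "C3"})],
            "minimal sets {C1,C2},{C1,C3}",
        )
        paths = {r.nodes for r in ident.proper_paths(dag, q)}
        check(("A", "C2", "C3", "Y") in paths, "path A<-C2->C3->Y present")
    elif name == "figure_2":
        check(msets == [frozenset({"C1"})], "minimal set {C1}")
        pat = imp.implied_pattern(dag, q, {"C1"})
        check(
            {v: e.verdict for v, e in pat.add_one.items()}
            == {"C2": "NO_CHANGE", "C3": "NO_CHANGE", "C4": "CHANGE", "C5": "CHANGE"},
            "add-one: change C4,C5 only",
        )
        check(pat.minus_one["C1"].verdict == "CHANGE", "minus-one change C1")
    elif name == "figure_3":
        check(msets == [frozenset({"C1", "C2", "C3"})], "minimal set {C1,C2,C3}")
    elif name == "figure_4":
        pat = imp.implied_pattern(dag, q, {"C1"})
        check(
            {v: e.verdict for v, e in pat.add_one.items()}
            == {"C2": "CHANGE", "C3": "NO_CHANGE", "C4": "CHANGE", "C5": "CHANGE"},
            "add-one: change C2,C4,C5; no change C3",
        )
        check(pat.minus_one["C1"].verdict == "CHANGE", "minus-one change C1")
    elif name == "figure_6":
        reports = ident.proper_paths(dag, q, {"C1", "C2*"})
        bad = [
            r
            for r in reports
            if r.nodes == ("A", "C2", "C3", "Y")
        ]
        check(
            bad and bad[0].status == "partially_blocked" and bad[0].blockers == ("C2",),
            "A<-C2->C3->Y partially blocked at C2 under {C1,C2*}",
        )
        check(
            not ident.is_sufficient(dag, q, {"C1", "C2*", "C3*"}),
            "{C1,C2*,C3*} insufficient",
        )
    elif name == "figure_8":
        check(msets == [], "no sufficient measured set")
        paths = {r.nodes for r in ident.proper_paths(dag, q)}
        check(("A", "ZU", "Y") in paths, "path A<-ZU->Y present")
    elif name == "figure_9":
        check(
            msets == [frozenset({"Age", "Comorbidity index"})],
            "minimal set {Age, Comorbidity index}",
        )
        sel = next(iter(dag.selection_nodes()))
        parents = set(dag.parents(sel))
        check(
            {"PKD", "Comorbidity index"} <= parents,
            "exposure and comorbidity parent the selection node",
        )
        check(
            ("Sex", "Death") not in dag.edges
            and ("Type of peritoneal dialysis", "Death") not in dag.edges,
            "no Sex->Death or TypePD->Death edge",
        )
    elif name == "figure_12":
        check(msets == [], "no sufficient measured set")
        paths = {r.nodes for r in ident.proper_paths(dag, q)}
        for want in (
            ("PKD", "MCI", "Death"),
            ("PKD", "MCI", "Frailty", "Death"),
            ("PKD", "MCI", "PD vs HD", "Frailty", "Death"),
            ("PKD", "PD vs HD", "Frailty", "Death"),
        ):
            check(want in paths, f"residual path {want} present")
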