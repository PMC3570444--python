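# Methods

This note documents the model and procedure `dagcie` implements, the
numerical and design choices behind it, what the synthetic-data generator
does and does not emulate, and known limitations.

## Graphs and identification

A `Dag` is an annotated causal diagram over named variables. Nodes are
`measured`, `latent` (unmeasured common causes, true values of mismeasured
covariates), or `selection` (participation variables conditioned upon
during data collection, e.g. registry membership). A measured node may be
declared a *proxy* of a latent node; the latent→proxy edge is part of the
graph (added implicitly if the user omits it), and the measurement-noise
parent is represented by the annotation rather than a mandatory extra
node — declaring it explicitly is equivalent.

Blocking follows d-separation: a non-collider on a path blocks it when
conditioned; a collider blocks unless it or one of its descendants is
conditioned. Two extensions:

* **Selection nodes are always conditioned.** Every query appends them to
  the conditioning set, so selection-induced collider paths (A→S←C→Y)
  are open unless blocked elsewhere.
* **Proxy conditioning partially blocks.** Conditioning on a proxy C\*
  of a latent non-collider C yields path status `partially_blocked`
  rather than `blocked`. Partial blocking counts as *open* for
  d-separation (the latent itself is unconditioned) and as *not blocked*
  for sufficiency, because residual bias flows through the latent.

An adjustment set (measured, non-selection variables that descend from
neither exposure nor outcome) is *sufficient* when every noncausal
exposure–outcome path is fully blocked under it plus the selection nodes;
*minimally sufficient* when no member can be dropped. Enumeration is
exhaustive over subsets of the candidate pool, ordered by size then
lexicographically; pools larger than 20 variables are refused with an
explicit error — this is a desk-scale tool for the small DAGs typical of
clinical epidemiology, not a structure-learning engine. Correctness is
cross-checked in the test suite against two independent algorithms:
reachability-based d-separation (`networkx.is_d_separator`) and the
adjustment criterion on the proper-backdoor graph.

### c-equivalence

Two adjustment sets are compared by the collection of paths left
unblocked under each (open paths keyed by their node sequence; partially
blocked paths also by where they are partially blocked, since moving the
partial block changes the transmitted bias; fully blocked paths are
dropped — blocker identity is estimand-irrelevant). Identical collections
with no residual noncausal path (in particular, any two sufficient sets)
are `equivalent`; different collections are `not_equivalent`; identical
but nonempty residual noncausal collections with different exposure-
associated membership are `not_equivalent_amplification` — the sets leave
the same bias paths open but amplify them differently because they carry
different "instrument strengths". The amplification test is qualitative
(a flag, not a magnitude): a variable is instrument-like when it is
marginally d-connected to the exposure. Marginal association (rather
than, say, exposure ancestry) is used deliberately: a child of a
confounder, e.g. C3 under C2→C3 with C2→A, predicts the exposure and
participates in amplification even though it is not an exposure ancestor.

## Implied add-one / minus-one patterns

For a working set S, the implied pattern assigns each variable a verdict:

* **add-one** (every measured non-selection variable outside S, including
  mediators and other exposure descendants — they are conditioned in the
  sweep even though they are ineligible for sufficient sets):
  `CHANGE` iff conditioning S∪{v} alters the unblocked-path collection,
  with reason codes `CONFOUNDER_BLOCKING` (an open noncausal path becomes
  blocked), `MEDIATOR_BLOCKING` (an open causal path becomes blocked),
  `COLLIDER_OPENING` (a blocked path opens), `PROXY_PARTIAL` (a partial
  blocking appears, disappears, or moves), or `BIAS_AMPLIFICATION`
  (collection unchanged, residual noncausal paths remain, v is
  exposure-associated). `NO_CHANGE` otherwise.
* **minus-one** (every member of S): `CHANGE` iff the collection under
  S∖{v} differs, with the same reason semantics (computed on the
  transition from the depleted to the full set so the codes describe v's
  role). For a minimally sufficient S every member is `CHANGE` by
  construction.

"Change" is defined graph-side as a difference in the unblocked-path
collection; under faithfulness this is exactly an estimand change for a
collapsible estimator. Amplification-reasoned changes are real but of
unknown magnitude and direction — they may be numerically zero in a
particular parameterisation — which the downstream asymmetric rule
absorbs (an unobserved implied change only flags). Incidental
cancellations are likewise handled downstream, not in the graph logic.

## Estimation

* **RD** (default): exposure coefficient of an OLS linear probability
  model of the binary outcome on exposure plus adjustment covariates,
  with an HC1 sandwich variance and a 95% Wald normal CI. The flavour of
  robust variance and the CI construction are this package's documented
  choice.
* **RR**: exponentiated exposure coefficient of a modified-Poisson model
  (GLM, Poisson family, log link) with the same robust variance; zero
  outcome events in either exposure arm or a non-converged fit raise an
  explicit model-failure error rather than returning a number.
* The odds ratio is deliberately not offered: it is non-collapsible and
  would change on adding outcome-associated non-confounders, breaking the
  pattern logic.

Complete cases only, with the count reported. Constant covariate columns
are dropped (absorbed by the intercept); genuinely collinear designs
raise an error naming the offending columns. Categorical covariates enter
as reference-coded indicator blocks added/removed as a unit. A failed fit
inside a sweep yields an unusable record (excluded from consistency
scoring) instead of aborting the sweep.

A change is *meaningful* when |Δ| strictly exceeds the threshold band:
`absolute` (value on the estimate's scale; default ±0.01 for the RD,
a cumulative-incidence difference that would warrant clinical attention)
or `relative` (fraction of the base estimate; the conventional 10% rule).
Boundary deltas are not meaningful; the strict inequality is arbitrary
but stated. Relative rules are undefined at a zero base estimate and say
so loudly.

## Bootstrap stability

Point-estimate classifications ignore sampling error, so patterns can
flip under resampling. The nonparametric bootstrap (default B = 2000;
tests and examples use smaller B and state it) resamples subjects with
replacement using one shared index stream for all variables, refits the
base estimate *within each resample* (the deltas are within-resample;
bootstrapping the patterns, not the point estimates, is this package's
convention where the procedure's description is ambiguous), classifies
each delta with the same rule, and reports the per-variable proportion of
usable resamples beyond the threshold. Resamples with failed fits are
dropped from that variable's denominator; variables retaining fewer than
half their resamples are flagged unstable. The report stores the raw
per-resample deltas, so proportions can be recomputed under other
thresholds without refitting (and are provably monotone in the
threshold). Percentile bootstrap CIs are deliberately not produced; the
bootstrap serves pattern stability only.

The optional majority sensitivity rule replaces each add-one meaningful
flag by `proportion > cutoff` (default 0.5, strict; the cutoff is
arbitrary and configurable). Minus-one records are never revised — an
absent implied change is already tolerated by weak faithfulness — only
reported.

## Consistency and iteration

Per variable: implied `NO_CHANGE` with an observed meaningful change is
`INCONSISTENT`; implied `CHANGE` without an observed meaningful change is
`FLAGGED_WEAK_FAITHFULNESS`; otherwise `OK`. A DAG is inconsistent iff it
has at least one `INCONSISTENT` locus; flags alone never reject a DAG.
This asymmetry is the procedure's core safeguard: a missing observed
change may be an incidental cancellation or a sub-threshold effect, so
the arrow is kept and labelled for other research teams.

`run_workflow` evaluates every candidate prior DAG on *its own*
lexicographically-first smallest minimal set (recomputing observed
patterns per candidate; a candidate with no sufficient measured set is
evaluated on the working DAG's set and labelled as such), additionally
compares estimates across a candidate's multiple minimal sets (a
meaningful cross-set difference contradicts the c-equivalence that DAG
implies and counts as inconsistency), drops inconsistent candidates, and
iterates with memoization and an iteration bound until stable.
`final_dags` prefers consistent DAGs with *no* weak-faithfulness flags
when at least one exists — matching how the pattern evidence favours the
generating graph over a superset graph whose extra implied changes never
materialise — while every consistent DAG remains reported (with its
flags) in `all_consistent`; presenting several final DAGs is an expected
outcome, not an error. When no prior DAG is consistent the result is
`unresolved` with all inconsistency loci listed: the tool deliberately
never invents DAG edits, since post hoc revision is where the procedure
is most easily abused.

## Synthetic data generator

The simulator attaches a structural-equation model to a DAG: every node
is linear in its parents, either `bernoulli_linear` (binary, success
probability = intercept + Σ coefficient·parent) or `gaussian_linear`
(continuous covariates). Linearity in probability is the point: it makes
the risk difference exactly collapsible, so the interventional RD equals
the sum over directed exposure→outcome paths of coefficient products
(`analytic_rd`), and the exact population value of the adjusted
linear-probability estimator — including residual-confounding, selection,
proxy, and amplification bias — is computable by weighted least squares
on the exhaustively enumerated binary joint distribution
(`population_adjusted_rd`). These two oracles anchor every estimation
test. Construction-time validation keeps all reachable probabilities
inside (0.01, 0.99) by interval arithmetic over parent supports and
forbids zero coefficients (faithfulness by construction). Proxies are
generated from their latent target with independent misclassification
(default 10%); selection nodes are drawn and then applied as row filters
(only rows with every selection variable = 1 are emitted, with pre- and
post-filter counts reported); latent columns are excluded from the
emitted dataset and available only through an explicit oracle output.

The fixture library reconstructs the canonical worked examples: the
confounding/mediation benchmark and its variants (`figure_1` …
`figure_4`), its measurement-error version with two proxied confounders
(`figure_6`), a residual-confounding version with a strong latent common
cause (`figure_8`), and a registry-style example with a selection node
(`figure_9`) and its latent-proxy variant with no sufficient measured set
(`figure_12`). Each fixture carries its defining constraints (minimal
sets, named paths, implied verdicts) and re-derives them through the
identification machinery at load time; a fixture that violates its
constraints cannot load. In `figure_4` the shared child of exposure and
outcome is a collider with an extra parent — the configuration whose
add-one pattern (change for the collider, no change for its parent)
distinguishes it from the confounding variants at the same working set.
Fixture coefficients were fixed once, using the exact population oracle,
so that every implied-`CHANGE` corresponds to an analytic delta above
0.02 (double the default threshold) and every implied-`NO_CHANGE` to an
analytic delta of exactly 0; this separates graph-logic behaviour from
sampling noise at the sample sizes the tests use (2×10⁴–2×10⁵ rows,
chosen so the whole suite and the acceptance script run comfortably on a
single CPU). In the registry-style fixtures the exposure has no direct
effect on the outcome, so the true RD is 0 while selection and
confounding push the crude RD near +0.14 — adjustment on the minimal set
recovers the null exactly in population.

What the generator does **not** emulate: real registry data's missing
values, continuous and time-to-event outcomes, covariate interactions and
non-linear mechanisms, non-independent measurement error, and
informative censoring. Passing tests therefore demonstrate that the
procedure's logic is correct under its stated assumptions
(compatibility, faithfulness, correct model specification, collapsible
estimator), not that it is robust to their violation on real data.

## Known limitations

* Total effects only; no direct/indirect effect decomposition.
* No regression model-specification checking; the usual diagnostics
  apply and are the user's responsibility.
* No DAG-discovery: candidate DAGs come from the user, and when none is
  consistent the tool reports rather than repairs.
* Qualitative amplification detection only; no magnitude or sign.
* Exhaustive minimal-set enumeration is exponential and capped at 20
  candidate variables.
* The bootstrap quantifies sampling variability of the patterns, not of
  the final estimate after selection; post-selection estimates remain
  over-precise, as with any a posteriori variable selection.
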