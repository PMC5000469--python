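# Methods

`attrirules` implements a two-stage rule-ensemble analysis for discovering
risk subgroups behind a binary study-withdrawal outcome, together with the
synthetic cohort machinery needed to validate every stage without access to
real participant data, and a conventional logistic-regression baseline for
comparison.

## The model

A *rule* is a conjunction of conditions on participant covariates — a
half-open threshold interval per numeric covariate (`maternal_age < 27.5`)
and a proper level subset per categorical covariate (`country != Finland`).
A participant *endorses* a rule when every condition holds; endorsers form
the rule's subgroup.  A condition evaluated on a missing value is false, so
records missing a conditioned covariate never endorse — a subgroup defined
by "smoked during pregnancy" does not absorb records with unknown smoking
status.

**Stage 1 — rule generation.**  Candidate rules are harvested from an
ensemble of binary recursive-partitioning trees.  Each tree is grown on a
bootstrap resample (with replacement, full cohort size) by greedy
best-first splitting maximizing the Gini impurity decrease of the outcome,
with a random feature subset per split (`ceil(sqrt(p))` features by
default).  Tree size is randomized: each tree draws its leaf limit
uniformly from {2, …, `max_leaves`} (default 8), so the pool mixes shallow,
broad rules with deeper interactions.  Numeric thresholds sit at midpoints
of adjacent observed values (hence 27.5-style cutoffs); categorical splits
are one-level-versus-rest, matching the form of the printed withdrawal
rules.  Every non-root node contributes the conjunction of conditions on
its root path (a leaves-only mode exists); rules are simplified (one
interval per feature, intersected level subsets), unsatisfiable
conjunctions dropped, and exact duplicates removed across the forest.
A `feature_mode="tree"` variant draws the feature subset once per tree
(classic random subspaces) instead of per split; it is slower to reduce
impurity but materially better at surfacing conjunctions of individually
weak factors, because trees that never see the dominant predictors must
work with the weak ones (see *Recovery behaviour* below).

Missing values during tree growth: records missing the split feature are
excluded from that split's evaluation and routed with the larger child.
Evaluation of an extracted rule treats conditions on missing values as
false.  The two conventions coincide exactly on complete data, which is
where the leaf-rule/tree-routing equivalence is asserted; on incomplete
data a rule's subgroup is deliberately the conservative (observed-only)
one.

**Stage 2 — rule pruning.**  With the pool encoded as an n×q binary
endorsement matrix `R` and outcome `y`, the pruned model minimizes the
L1-penalized logistic negative log-likelihood

    (1/n) Σᵢ [ log(1 + exp(ηᵢ)) − yᵢ ηᵢ ] + λ‖β‖₁ ,  η = β₀ + Rβ,

with an unpenalized intercept.  The logistic loss (rather than the
squared-error form of the generic lasso display) is the appropriate choice
for the binary outcome.  Constant and exactly duplicated columns are
dropped before fitting (first occurrence kept).  λ is chosen by stratified
k-fold cross-validation (default k = 10) over a 25-point log-spaced grid
descending from λ_max (the smallest penalty giving the empty model) to
0.01·λ_max, using the one-standard-error rule by default — sparser models
suit subgroup interpretation; a "min" rule is available.  Rules with
non-zero coefficients are the selected risk-predictive rules, labeled
risk-increasing (β > 0) or risk-decreasing (β < 0).  Binary indicator
columns are not standardized by default (they share a scale; standardizing
would make the effective penalty support-dependent); a flag exists.

**Solver.**  The penalized fits use a proximal-Newton / coordinate-descent
scheme specialized to binary designs: an outer IRLS loop forms the local
quadratic approximation (weights p(1−p), working residual y−p) and an
inner cyclic coordinate-descent loop solves the penalized weighted
least-squares subproblem with soft-thresholded updates.  Coordinate steps
move along weighted-centered columns with the intercept compensated
algebraically — for binary columns the centering correction is
proportional to the weights and carried as one scalar, so updates stay
sparse while the dominant intercept/column collinearity of high-support
indicators disappears.  Single-penalty fits converge the working set and
then run a KKT screening pass over all coordinates, admitting violators
until none remain; path fits additionally seed the working set by the
sequential strong rule `|gⱼ| > 2λ − λ_prev` with warm starts between
penalties.  Tolerances: final fits stop at a 1e-7 maximum coefficient
change per re-quadratization (refined until the exact KKT residual is
≤ 1e-8, capped at 1e5 sweeps); cross-validation path fits default to 1e-4,
because penalty selection compares held-out losses whose fold-to-fold
standard errors (≈1e-3) dwarf the effect of 1e-4 coefficient error, and
the tighter tolerance multiplies CV cost by roughly an order of magnitude
without changing the selected penalty.

**Profiling.**  For the final rule set the package reports, per rule, the
endorsement count and subgroup withdrawal rate with a direction label
(increasing/decreasing versus the overall rate; exact ties are labeled
neutral, a case the real analysis never produced); the fraction of the
population endorsing no rule and that group's withdrawal rate; and the q×q
redundancy matrix M where `M[i,j]` is the proportion of rule-i endorsers
who also endorse rule j.  M is derived from integer joint-endorsement
counts, so the identities `M[i,j]·nᵢ = M[j,i]·nⱼ` and a unit diagonal hold
exactly; rows with zero endorsers are flagged undefined (NaN), never
silently zero.

**Baseline.**  The comparison analysis is a complete-case maximum-
likelihood logistic regression with blockwise covariate entry
(demographics; pregnancy/lifestyle; father's participation; maternal
reactions with the anxiety × risk-perception interaction), Wald standard
errors, odds ratios and 95% CIs per term, a likelihood-ratio model
chi-square against the intercept-only model, and classification accuracy
at the 0.5 cutoff.  Multiple imputation is out of scope; the per-record
missing-data count remains available as a covariate.  The concordance
table flags covariates found only by the regression or only inside
selected rules.

## The synthetic cohort generator

The generator draws covariates independently from declared marginals,
applies per-covariate Bernoulli missingness masks, and draws the outcome
from a logistic model: baseline log-odds plus the summed effects of the
planted rules a record endorses (effects add on the logit scale, matching
the additive form of the pruning model).  The outcome is drawn before the
covariates are masked; planted rules are evaluated on the clean covariate
values plus the mask-derived missing-data count, so missingness never
perturbs the outcome except through that explicit channel — and rules
conditioning on the missing count are meaningful.  Sub-streams for
covariates, masks, and outcome are spawned from one seed, so runs are
bit-reproducible and changing, say, a missingness rate leaves the outcome
stream untouched.

`teddy_like_spec(n, seed)` encodes the study conditions the package is
validated under: marginals follow the published descriptive table of the
withdrawal study's general-population sample — country (23.6 / 3.8 / 34.2
/ 38.5% for Finland/Germany/Sweden/US), child sex ≈ 50/50, maternal age
N(30.4, 5.2²) truncated to 15–50, smoking 13.0%, alcohol-per-month pmf
(0.817, 0.075, 0.075, 0.033) on {0, 1, 2, 3}, employment (worked all
trimesters) 47.5%, father participation 91.5%, accurate risk perception
59.5%, anxiety score N(39.1, 9.9²) truncated to 20–80 (the instrument's
range), and per-covariate missingness rates taken from the printed
"data missing" rows (3–7%).  The negative-life-events count has no
published marginal; it uses a Poisson(1.5) capped at 10, a typical
stressful-life-events tally.  The eight packaged withdrawal rules are
planted with effects +1.0 (rules 1–4, risk-increasing) and −1.0 (rules
5–8, risk-decreasing) log-odds, satisfying the "strong effect" regime
(|effect| ≥ 0.8) used throughout validation.  The baseline log-odds is
logit(0.2), the approximate first-year withdrawal rate, *defined for
records endorsing no rule*; because the risk-decreasing rules cover most
of the population, the realized overall rate lands near 0.12 — this is a
property of the planted-effect model, not a calibration target.

`planted_truth` returns each rule's expected endorsement probability
(analytic: product of per-condition probabilities over independent
covariates; conditions on the missing count use the exact Poisson-binomial
pmf of the masks) and expected subgroup withdrawal rate (exact enumeration
over rule-endorsement patterns when rules share no features; otherwise a
Rao-Blackwellized Monte Carlo estimate averaging exact per-record
probabilities, flagged `"mc"`).

What the generator does **not** emulate: covariate dependence (all
covariates independent; an analysis on real data would face correlated
predictors), family/site clustering, longitudinal visit-level dropout, and
informative missingness (masks are independent of values and outcome).
Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted structure under clean conditions, not
performance guarantees on real cohort data.

## Recovery behaviour and validation scales

Validation simulations use n = 10,000 cohorts; 20 replicate seeds for the
end-to-end recovery and null-selection checks; n = 50,000 for
closed-form/moment checks; and n = 100,000 for distributional fidelity
(KS/chi-square at α = 0.001).  These sizes keep the full suite within a
few minutes of compute while leaving Monte Carlo error far below the
asserted margins.

End-to-end recovery is measured by endorsement-pattern overlap: a planted
rule counts as recovered when some selected rule's endorser set has
Jaccard similarity ≥ 0.5 with the planted rule's.  With default settings
the pipeline recovers 5–7 of the 8 planted rules per replicate; the three
hardest are the conjunctions built from individually weak factors.
Syntactic recovery (same feature set, thresholds within a fraction of each
covariate's spread: ±1.5 years of age, ±3 anxiety points, exact level
subsets) is checked at the pool level on a diverse random-subspace forest
(600 trees, up to 16 leaves, `feature_mode="tree"`, 10 replicate seeds):
mean per-rule recovery is ≈0.93, with seven of the eight rules found in
≥80% of replicates.  The known hard case is the rule joining country,
alcohol frequency, and negative life events — three factors whose
individual impurity decreases are dominated by smoking, age, and anxiety —
which per-split feature sampling never extracts and per-tree sampling
finds in ≈60% of replicates.  This asymmetry is a real property of greedy
impurity-driven rule generation, not a tuning artifact, and is the reason
the per-tree mode exists.

## Numerical and degenerate-input conventions

* Split ties are broken deterministically: lowest feature index, then
  smallest threshold / earliest level.  Pure nodes and nodes smaller than
  2·`min_leaf` stop splitting; an all-constant cohort yields a single-leaf
  tree and contributes no rules.
* `crude_odds_ratio` refuses zero cells rather than applying a continuity
  correction; percent displays round half away from zero, matching the
  published table's formatting.
* Cross-validation folds are stratified on the outcome by dealing
  class-permuted records across folds with a running counter, so any
  k ≤ n yields non-empty folds (leave-one-out included); a training split
  missing an outcome class raises with guidance to reduce k.
* An empty selected-rule set is a legitimate pruning outcome (returned
  with a warning); zero-endorser subgroups propagate as explicit
  undefined flags.
* Pipeline stages derive independent seeds from the single run seed, so
  changing forest size does not perturb the generated cohort; outputs are
  plain CSV/JSON with SHA-256 checksums in the run manifest, and identical
  configurations reproduce identical outputs byte for byte.

## Known limitations

* Rule generation is bagged (bootstrap + feature subsampling), not
  gradient-boosted; linear terms, winsorized soft rules, and multiway
  categorical splits are out of scope.
* No post-selection inference is offered for selected rules — subgroup
  rates are descriptive, and the lasso's selection events are not
  accounted for.
* The baseline is complete-case only; with covariate missingness of a few
  percent per column, roughly 15–20% of records drop from the regression,
  and estimates inherit whatever bias the missingness mechanism implies.
* Near-duplicate (but not identical) endorsement columns survive
  deduplication and can share credit under the L1 penalty; the redundancy
  matrix is the tool for reading such overlap after selection.
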