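# attrirules

Rule-based subgroup discovery for study-withdrawal (attrition) risk in
cohort studies, with a logistic-regression baseline for comparison.

Longitudinal studies lose participants, and regression models of dropout
describe the *average* effect of each risk factor.  Epidemiologists
planning retention interventions often need something different: the
*subgroups* — combinations of factor ranges — whose members leave at
distinctly higher or lower rates.  `attrirules` implements the
rule-ensemble (RuleFit-style) answer for a binary first-year-withdrawal
outcome over mixed demographic, behavioral, and psychosocial covariates,
of the kind collected at inception of a pediatric cohort study.

A **rule** is a conjunction such as

```
maternal_age < 27.5 AND country != Finland
```

A participant *endorses* a rule when every condition holds; the endorsers
form the rule's subgroup.  The analysis has two stages:

1. **Rule generation** — grow a bootstrapped, feature-subsampled ensemble
   of recursive-partitioning (CART-style, Gini) trees with randomized
   sizes, and harvest one candidate rule per non-root node (the
   conjunction along its root path), simplified and deduplicated.
2. **Rule pruning** — encode the q candidates as binary indicator columns
   R₁…R_q and select a sparse predictive subset by L1-penalized logistic
   regression,

   min over (β₀, β) of (1/n) Σᵢ [log(1 + e^{ηᵢ}) − yᵢ ηᵢ] + λ‖β‖₁,
   η = β₀ + Rβ,

   with λ chosen by stratified cross-validation (one-standard-error rule
   by default).  Selected rules are labeled risk-increasing (β > 0) or
   risk-decreasing (β < 0).

The surviving subgroups are then **profiled**: per-rule withdrawal rates
versus the overall rate, the uncovered fraction of the population, and
the q×q redundancy matrix (share of rule-i endorsers who also endorse
rule j).  A complete-case multivariable logistic regression with
blockwise covariate entry and an anxiety × risk-perception interaction
serves as the baseline, and a concordance table flags factors found only
by one method.

Because real withdrawal data are confidential, the package ships a
first-class synthetic cohort generator that reproduces the published
study's covariate marginals and plants the eight published withdrawal
rules with signed log-odds effects — every pipeline stage is validated
against this planted ground truth.  See `docs/methods.md` for the model
details and design choices.

## Worked example

Profile the eight packaged withdrawal rules on a synthetic cohort of
10,000 with those same rules planted (±1.0 log-odds):

```python
import attrirules as ar

spec = ar.teddy_like_spec(10_000, seed=1)
cohort = ar.generate_cohort(spec)
rules = ar.load_teddy_rules(cohort.schema)
profiles, overall, coverage = ar.profile_rules(rules, cohort)
print(f"overall withdrawal rate: {overall:.3f}")
for i, p in enumerate(profiles, 1):
    print(f"rule {i}: n={p.n_endorsing:5d}  rate={p.outcome_rate:.3f}  {p.direction}")
print(f"uncovered: {coverage.fraction_uncovered:.1%} of the cohort, "
      f"rate {coverage.uncovered_outcome_rate:.3f}")
```

prints

```
overall withdrawal rate: 0.114
rule 1: n= 2174  rate=0.283  increasing
rule 2: n=  126  rate=0.508  increasing
rule 3: n=  231  rate=0.260  increasing
rule 4: n=  941  rate=0.379  increasing
rule 5: n= 3591  rate=0.055  decreasing
rule 6: n=  751  rate=0.063  decreasing
rule 7: n= 5710  rate=0.064  decreasing
rule 8: n= 5895  rate=0.035  decreasing
uncovered: 12.1% of the cohort, rate 0.156
```

Every risk-increasing rule's subgroup withdraws well above the overall
rate and every risk-decreasing rule's below it — the directions the rules
were planted with.  About an eighth of the cohort endorses no rule, and
that uncovered group withdraws at an above-average rate, mirroring the
qualitative finding that the rule set leaves a small, relatively
high-risk remainder unexplained.

To learn rules from scratch instead of evaluating the fixtures:

```python
forest = ar.grow_forest(cohort, ar.ForestParams(n_trees=200, seed=7))
pool = ar.extract_rules(forest)                       # ~1,100 candidates
model = ar.prune_rules(pool, cohort, ar.PruneConfig(seed=3))
for s in model.selected:
    print(f"{s.coefficient:+.2f}  {ar.rule_to_text(s.rule, cohort.schema)}")
```

The same flow is available from the shell:

```bash
attrirules demo --out out/demo --n 10000 --seed 1     # fixture profiling
attrirules run-all --config config.yaml --seed 1      # full pipeline
```

`run-all` executes simulate/load → discover → prune → profile → baseline,
writes plain CSV/JSON outputs plus optional plots, and ends with a
manifest of per-stage timings and SHA-256 checksums; identical
configurations reproduce identical outputs.

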