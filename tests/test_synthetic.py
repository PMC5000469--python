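"""Synthetic cohort generator: determinism, marginal and effect fidelity."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from attrirules.rules import Condition, Rule
from attrirules.synthetic import (
    CategoricalMarginal,
    CountMarginal,
    PoissonMarginal,
    SyntheticSpec,
    TruncNormalMarginal,
    generate_cohort,
    generate_with_truth,
    planted_truth,
    spec_from_yaml,
    spec_to_yaml,
    teddy_like_spec,
)


def small_spec(n, seed=0, rules=(), missingness=None):
    marginals = {
        "maternal_age": TruncNormalMarginal(30.4, 5.2, 15, 50),
        "smoking": CategoricalMarginal(("no", "yes"), (0.85, 0.15)),
        "negative_life_events": PoissonMarginal(1.5, cap=10),
    }
    return SyntheticSpec(n, marginals, float(logit(0.2)), tuple(rules),
                         missingness or {}, seed)


def test_empty_cohort():
    assert generate_cohort(small_spec(0)).n == 0


def test_determinism_same_spec_same_cohort():
    a = generate_cohort(small_spec(500, seed=42))
    b = generate_cohort(small_spec(500, seed=42))
    pd.testing.assert_frame_equal(a.df, b.df)
    c = generate_cohort(small_spec(500, seed=43))
    assert not a.df.equals(c.df)


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        small_spec(-1)
    with pytest.raises(ValueError):
        small_spec(5, missingness={"unknown": 0.1})
    with pytest.raises(ValueError):
        small_spec(5, missingness={"smoking": 1.5})
    with pytest.raises(ValueError):
        CategoricalMarginal(("a", "b"), (0.6, 0.5))
    rule = Rule((Condition("not_a_feature", "<", 1.0),))
    with pytest.raises(ValueError, match="unknown feature"):
        small_spec(5, rules=((rule, 1.0),))


def test_baseline_rate_matches_logit():
    """No planted rules: empirical rate ~ expit(baseline) within 3 SE."""
    cohort = generate_cohort(small_spec(50_000, seed=7))
    se = np.sqrt(0.2 * 0.8 / 50_000)
    assert abs(cohort.outcome.mean() - 0.2) < 3 * se


def test_planted_rule_shifts_endorsers_rate():
    """Endorsers' rate ~ expit(logit(0.2) + 1) ~ 0.405 within MC error."""
    rule = Rule((Condition("maternal_age", "<", 27.5),))
    spec = small_spec(50_000, seed=3, rules=((rule, 1.0),))
    cohort, truth_df, endorse, p = generate_with_truth(spec)
    sel = endorse[:, 0]
    expected = float(expit(logit(0.2) + 1.0))
    assert expected == pytest.approx(0.4046, abs=1e-3)
    se = np.sqrt(expected * (1 - expected) / sel.sum())
    assert abs(cohort.outcome[sel].mean() - expected) < 3 * se


def test_planted_truth_analytic_cases():
    spec = small_spec(10)
    truth = planted_truth(spec)
    assert truth.overall_rate == pytest.approx(0.2)
    assert truth.overall_method == "analytic"

    rule = Rule((Condition("smoking", "in", frozenset({"yes"})),))
    spec = small_spec(10, rules=((rule, 1.0),))
    truth = planted_truth(spec)
    assert truth.rules[0].endorsement_prob == pytest.approx(0.15)
    assert truth.rules[0].expected_rate == pytest.approx(float(expit(logit(0.2) + 1)))

    # two-condition rule on independent covariates: product of probabilities
    rule2 = Rule((Condition("smoking", "in", frozenset({"yes"})),
                  Condition("maternal_age", "<", 27.5)))
    spec2 = small_spec(10, rules=((rule2, 1.0),))
    p_age = TruncNormalMarginal(30.4, 5.2, 15, 50).cdf(27.5)
    expected = 0.15 * p_age
    assert planted_truth(spec2).rules[0].endorsement_prob == pytest.approx(expected)
    # Monte Carlo cross-check of the independence product
    spec_mc = dataclasses.replace(spec2, n=100_000, seed=5)
    _, _, endorse, _ = generate_with_truth(spec_mc)
    emp = endorse[:, 0].mean()
    assert abs(emp - expected) < 3 * np.sqrt(expected * (1 - expected) / 100_000)


def test_planted_truth_mc_for_overlapping_rules():
    """Rules sharing a feature force the Monte Carlo path; rates stay ordered."""
    r_low = Rule((Condition("maternal_age", "<", 27.5),))
    r_high = Rule((Condition("maternal_age", "<", 35.0),))
    spec = small_spec(10, rules=((r_low, 1.0), (r_high, 0.5)))
    truth = planted_truth(spec, mc_n=50_000)
    assert truth.rules[0].method == "mc"
    assert truth.rules[0].expected_rate > truth.rules[1].expected_rate > 0.2


def test_masking_never_alters_outcomes():
    """Outcome stream is independent of missingness (no missing-count rules)."""
    rule = Rule((Condition("smoking", "in", frozenset({"yes"})),))
    base = small_spec(2_000, seed=9, rules=((rule, 1.0),))
    masked = dataclasses.replace(base, missingness={"smoking": 0.3})
    a, b = generate_cohort(base), generate_cohort(masked)
    assert np.array_equal(a.outcome, b.outcome)
    assert b.df["smoking"].isna().sum() > 0
    assert a.df["smoking"].isna().sum() == 0


def test_missing_count_rules_use_mask_counts():
    rule = Rule((Condition("n_missing", ">=", 1.0),))
    spec = small_spec(30_000, seed=13, rules=((rule, 2.0),),
                      missingness={"smoking": 0.2})
    cohort, truth_df, endorse, _ = generate_with_truth(spec)
    assert np.array_equal(endorse[:, 0], cohort.missing_counts >= 1)
    sel = cohort.missing_counts >= 1
    assert cohort.outcome[sel].mean() > cohort.outcome[~sel].mean()
    # Poisson-binomial endorsement probability is exact here: P(mask) = 0.2
    truth = planted_truth(spec)
    assert truth.rules[0].endorsement_prob == pytest.approx(0.2)


def test_marginal_fidelity_at_large_n():
    """KS / chi-square fidelity checks at n = 100,000, alpha = 0.001."""
    spec = teddy_like_spec(100_000, seed=21)
    cohort = generate_cohort(spec)
    df = cohort.df
    m = spec.marginals["maternal_age"]
    ks = stats.kstest(df["maternal_age"], m._dist().cdf)
    assert ks.pvalue > 0.001
    cm = spec.marginals["country"]
    counts = df["country"].value_counts()
    obs = np.array([counts.get(l, 0) for l in cm.levels])
    chi = stats.chisquare(obs, np.array(cm.probs) * cohort.n)
    assert chi.pvalue > 0.001
    # capped Poisson count
    pm = spec.marginals["negative_life_events"]
    vals = df["negative_life_events"].to_numpy()
    support = np.arange(0, 11)
    probs = stats.poisson(pm.mean).pmf(support)
    probs[-1] += stats.poisson(pm.mean).sf(10)
    obs = np.array([(vals == v).sum() for v in support])
    chi = stats.chisquare(obs, probs * cohort.n)
    assert chi.pvalue > 0.001


def test_teddy_like_spec_structure_and_effects():
    spec = teddy_like_spec(3757, seed=2)
    cohort = generate_cohort(spec)
    assert cohort.n == 3757
    # smoking marginal within 3 SE of the declared probability
    p_smoke = spec.marginals["smoking"].probs[1]
    obs = (cohort.df["smoking"] == "yes").mean() / cohort.df["smoking"].notna().mean()
    assert abs(obs - p_smoke) < 3 * np.sqrt(p_smoke * (1 - p_smoke) / 3757)
    assert len(spec.planted_rules) == 8
    effects = [e for _, e in spec.planted_rules]
    assert effects == [1.0] * 4 + [-1.0] * 4
    # rule 1 endorsers (young, non-Finland) withdraw more often at large n
    big = generate_cohort(teddy_like_spec(20_000, seed=3))
    rule1 = spec.planted_rules[0][0]
    sel = rule1.endorsement(big.df)
    assert big.outcome[sel].mean() > big.outcome.mean()


def test_spec_yaml_round_trip(tmp_path):
    spec = teddy_like_spec(123, seed=9)
    path = tmp_path / "spec.yaml"
    spec_to_yaml(spec, path)
    again = spec_from_yaml(path)
    assert again.n == 123 and again.seed == 9
    assert set(again.marginals) == set(spec.marginals)
    assert [r.key() for r, _ in again.planted_rules] == \
        [r.key() for r, _ in spec.planted_rules]
    pd.testing.assert_frame_equal(generate_cohort(again).df,
                                  generate_cohort(spec).df)
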