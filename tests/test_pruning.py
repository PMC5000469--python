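"""Sparse logistic pruning: solver behavior, CV selection, end-to-end pruning."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from attrirules.cohort import Cohort, CovariateSchema, Variable
from attrirules.forest import RulePool
from attrirules.pruning import (
    CvResult,
    DegenerateFitError,
    PenalizedProblem,
    PruneConfig,
    PrunedModel,
    fit_sparse_logistic,
    kkt_violations,
    lambda_grid,
    lambda_max,
    logistic_objective,
    prune_rules,
    select_lambda_cv,
)
from attrirules.rules import Condition, Rule


def random_problem(n=200, q=8, seed=0, signal=None):
    rng = np.random.default_rng(seed)
    R = (rng.random((n, q)) < rng.uniform(0.1, 0.6, q)).astype(float)
    eta = -1.0 + (R @ signal if signal is not None else 0.0)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return R, y


def test_full_shrinkage_at_huge_lambda():
    R, y = random_problem(seed=1, signal=np.array([1.0] + [0.0] * 7))
    fit = fit_sparse_logistic(PenalizedProblem(R, y, 1e6))
    assert np.all(fit.beta == 0.0)
    assert fit.intercept == pytest.approx(float(logit(y.mean())), abs=1e-6)


def test_unpenalized_single_indicator_equals_crude_log_or():
    """lambda = 0, one binary predictor: the coefficient is the 2x2 log-OR."""
    # layout: x=1 -> 30 of 80 events; x=0 -> 15 of 120 events
    R = np.concatenate([np.ones(80), np.zeros(120)])[:, None]
    y = np.concatenate([np.ones(30), np.zeros(50), np.ones(15), np.zeros(105)])
    fit = fit_sparse_logistic(PenalizedProblem(R, y, 0.0))
    expected = math.log((30 * 105) / (50 * 15))
    assert fit.beta[0] == pytest.approx(expected, abs=1e-6)
    assert fit.intercept == pytest.approx(math.log(15 / 105), abs=1e-6)


def test_lambda_max_boundary():
    """The fit is empty exactly down to lambda_max and non-empty below it."""
    R, y = random_problem(n=500, seed=2, signal=np.array([1.5] + [0.0] * 7))
    lmax = lambda_max(R, y)
    assert len(fit_sparse_logistic(PenalizedProblem(R, y, lmax * 1.001)).selected) == 0
    assert len(fit_sparse_logistic(PenalizedProblem(R, y, lmax * 0.8)).selected) > 0
    grid = lambda_grid(lmax, 10, 0.01)
    assert np.all(np.diff(grid) < 0) and grid[0] == lmax


def test_warm_and_cold_starts_agree():
    R, y = random_problem(n=400, q=12, seed=3,
                          signal=np.array([1.0, -1.0] + [0.0] * 10))
    grid = lambda_grid(lambda_max(R, y), 8, 0.02)
    warm = None
    for lam in grid:
        prob = PenalizedProblem(R, y, lam)
        wf = fit_sparse_logistic(prob, warm=warm)
        cf = fit_sparse_logistic(prob)
        warm = (wf.beta, wf.intercept)
        assert wf.objective == pytest.approx(cf.objective, abs=1e-6)


def test_column_permutation_equivariance():
    R, y = random_problem(n=300, q=6, seed=4, signal=np.array([1.0, 0, -1.0, 0, 0, 0]))
    lam = 0.02
    fit = fit_sparse_logistic(PenalizedProblem(R, y, lam))
    perm = np.array([3, 0, 5, 1, 4, 2])
    fit_p = fit_sparse_logistic(PenalizedProblem(R[:, perm], y, lam))
    assert np.allclose(fit_p.beta, fit.beta[perm], atol=1e-6)


def test_degenerate_and_invalid_inputs():
    R = np.ones((10, 1))
    with pytest.raises(DegenerateFitError):
        fit_sparse_logistic(PenalizedProblem(R, np.ones(10), 0.1))
    with pytest.raises(ValueError, match="0/1"):
        PenalizedProblem(np.full((4, 1), 0.5), np.array([0, 1, 0, 1]), 0.1)
    with pytest.raises(ValueError):
        PenalizedProblem(np.ones((4, 1)), np.array([0, 1, 0]), 0.1)
    with pytest.raises(ValueError):
        PenalizedProblem(np.ones((4, 1)), np.array([0, 1, 0, 1]), -0.5)


def test_objective_never_worse_than_empty_model():
    R, y = random_problem(n=300, seed=6, signal=np.array([1.0] + [0.0] * 7))
    lam = 0.01
    fit = fit_sparse_logistic(PenalizedProblem(R, y, lam))
    empty = logistic_objective(R, y, np.zeros(R.shape[1]),
                               float(logit(y.mean())), lam)
    assert fit.objective <= empty + 1e-12


def test_loo_cv_runs_on_tiny_fixture():
    y = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
    R = np.column_stack([y, np.array([0, 1, 1, 0, 0, 1, 0, 1, 1, 0])]).astype(float)
    cv = select_lambda_cv(R, y, k=10, rng=0)
    assert cv.lambda_star in cv.lambdas
    assert cv.mean_loss.shape == cv.lambdas.shape


def test_cv_rejects_single_class_training_folds():
    R = np.ones((6, 1))
    y = np.array([1, 0, 0, 0, 0, 0], dtype=float)
    with pytest.raises(ValueError, match="single outcome class"):
        select_lambda_cv(R, y, k=5, rng=0)
    with pytest.raises(ValueError, match="unknown selection rule"):
        select_lambda_cv(R, y, k=2, rule="2se", rng=0)


def test_cv_result_invariants():
    with pytest.raises(ValueError):
        CvResult(np.array([1.0, 2.0]), np.zeros(2), np.zeros(2), 1.0, "min")
    with pytest.raises(ValueError):
        CvResult(np.array([2.0, 1.0]), np.zeros(2), np.zeros(2), 0.5, "min")


# ---------------------------------------------------------------------------
# prune_rules end to end


def _indicator_cohort(R: np.ndarray, y: np.ndarray):
    """Cohort with one binary covariate per column of R, plus rules reading them."""
    q = R.shape[1]
    variables = tuple(Variable(f"f{j}", "count", lo=0) for j in range(q))
    schema = CovariateSchema(variables, "withdrawn")
    df = pd.DataFrame({f"f{j}": R[:, j] for j in range(q)})
    df["withdrawn"] = y.astype(int)
    cohort = Cohort(schema, df)
    rules = [Rule((Condition(f"f{j}", ">=", 1.0),)) for j in range(q)]
    return cohort, rules


def test_perfect_predictor_rule_is_selected():
    rng = np.random.default_rng(8)
    R = (rng.random((400, 1)) < 0.4).astype(float)
    y = R[:, 0].copy()
    cohort, rules = _indicator_cohort(R, y)
    model = prune_rules(RulePool(tuple(rules)), cohort, PruneConfig(folds=5, seed=1))
    assert len(model.selected) == 1
    assert model.selected[0].coefficient > 0
    assert model.selected[0].direction == "increasing"


def test_duplicate_columns_deduplicated_before_fitting():
    rng = np.random.default_rng(9)
    x = (rng.random(300) < 0.5).astype(float)
    y = (rng.random(300) < np.where(x > 0, 0.7, 0.2)).astype(float)
    R = np.column_stack([x, x, np.ones(300)])  # duplicate + constant column
    cohort, rules = _indicator_cohort(R, y)
    model = prune_rules(RulePool(tuple(rules)), cohort, PruneConfig(folds=5, seed=2))
    assert model.q_candidates == 3
    assert model.q_fitted == 1
    assert len(model.selected) == 1


def test_empty_selection_warns_but_succeeds():
    rng = np.random.default_rng(10)
    R = (rng.random((300, 4)) < 0.3).astype(float)
    y = (rng.random(300) < 0.3).astype(float)  # pure noise
    cohort, rules = _indicator_cohort(R, y)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = prune_rules(RulePool(tuple(rules)), cohort,
                            PruneConfig(folds=5, seed=3))
    if not model.selected:  # overwhelmingly likely under pure noise + 1se
        assert any("no rules" in str(w.message) for w in caught)


def test_pruned_model_json_round_trip(tmp_path, tiny_schema):
    rule = Rule((Condition("maternal_age", "<", 27.5),
                 Condition("smoking", "in", frozenset({"yes"}))))
    cv = CvResult(np.array([0.2, 0.1]), np.array([0.5, 0.4]),
                  np.array([0.01, 0.01]), 0.1, "1se")
    from attrirules.pruning import SelectedRule
    model = PrunedModel((SelectedRule(rule, 0.7),), -1.2, 0.1, cv, 5, 4)
    path = tmp_path / "model.json"
    model.to_json(path, tiny_schema)
    again = PrunedModel.from_json(path, tiny_schema)
    assert again.selected[0].rule.key() == rule.key()
    assert again.selected[0].coefficient == pytest.approx(0.7)
    assert again.lambda_star == pytest.approx(0.1)
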