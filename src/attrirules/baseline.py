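"""Complete-case multivariable logistic regression baseline.

The comparison analysis: a maximum-likelihood logistic regression of
first-year withdrawal on the study covariates, with blockwise covariate
entry (demographics; pregnancy/lifestyle; father's participation;
maternal reactions including the anxiety x risk-perception interaction)
and Wald standard errors, odds ratios and 95% CIs per term, the
likelihood-ratio model chi-square, and classification accuracy at the
0.5 probability cutoff.

Only complete cases on the modeled covariates enter the fit; multiple
imputation is out of scope (the missing-data *count* is still available
as a covariate).  :func:`compare_with_rules` tabulates, per covariate,
whether it is a significant regression term and/or appears inside a
selected rule — the concordance check between the average-effects model
and the subgroup rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort, CovariateSchema
from .rules import Rule

__all__ = [
    "Term",
    "ModelSpec",
    "FitReport",
    "SeparationError",
    "teddy_model_spec",
    "fit_logistic_baseline",
    "compare_with_rules",
]


class SeparationError(RuntimeError):
    """The MLE diverges (separation); the offending term is named."""


@dataclass(frozen=True)
class Term:
    """One model covariate; ``ref`` names the reference level (categorical only)."""

    name: str
    ref: str | None = None


@dataclass(frozen=True)
class ModelSpec:
    terms: tuple[Term, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    blocks: tuple[tuple[str, ...], ...] | None = None

    def __post_init__(self) -> None:
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate model terms")
        for a, b in self.interactions:
            if a not in names or b not in names:
                raise ValueError(f"interaction ({a}, {b}) members must be main effects")
        if self.blocks is not None:
            flat = [n for blk in self.blocks for n in blk]
            unknown = set(flat) - set(names)
            if unknown:
                raise ValueError(f"blocks reference unknown terms {sorted(unknown)}")

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class FitReport:
    table: pd.DataFrame               # term, estimate, se, p_value, OR, CI bounds
    chi2: float                       # LR statistic vs intercept-only
    df: int
    p_value: float
    accuracy: float                   # at probability cutoff 0.5
    n_used: int                       # complete cases entering the fit
    block_loglik: tuple[float, ...]   # log-likelihood after each cumulative block
    term_covariates: dict = field(default_factory=dict, compare=False)


def teddy_model_spec() -> ModelSpec:
    """Default model for the TEDDY-like schema with blockwise entry.

    Blocks: demographics; pregnancy/lifestyle; father's participation;
    maternal reactions (risk-perception accuracy, anxiety, and their
    interaction).  Reference levels mirror the published table (US,
    male, non-smoker, did not work all trimesters, no dad
    participation, underestimated risk).
    """
    return ModelSpec(
        terms=(
            Term("country", ref="United States"),
            Term("sex", ref="male"),
            Term("maternal_age"),
            Term("smoking", ref="no"),
            Term("alcohol_per_month"),
            Term("employment", ref="no"),
            Term("negative_life_events"),
            Term("dad_participation", ref="no"),
            Term("risk_perception", ref="underestimate"),
            Term("anxiety_score"),
        ),
        interactions=(("anxiety_score", "risk_perception"),),
        blocks=(
            ("country", "sex", "maternal_age"),
            ("smoking", "alcohol_per_month", "employment", "negative_life_events"),
            ("dad_participation",),
            ("risk_perception", "anxiety_score"),
        ),
    )


def _term_columns(df: pd.DataFrame, schema: CovariateSchema, term: Term
                  ) -> dict[str, pd.Series]:
    var = schema.variable(term.name)
    if var.kind == "categorical":
        ref = term.ref if term.ref is not None else var.levels[0]
        if ref not in var.levels:
            raise ValueError(f"reference level {ref!r} not a level of {term.name!r}")
        cols = {}
        for lev in var.levels:
            if lev == ref:
                continue
            ind = pd.Series(np.where(df[term.name].isna(), np.nan,
                                     (df[term.name] == lev).astype(float)),
                            index=df.index)
            cols[f"{term.name}[{lev}]"] = ind
        return cols
    return {term.name: df[term.name].astype(float)}


def _design(df: pd.DataFrame, schema: CovariateSchema, spec: ModelSpec,
            term_names: list[str]):
    """Design columns + map from design column to its source covariates."""
    cols: dict[str, pd.Series] = {}
    origin: dict[str, tuple[str, ...]] = {}
    per_term: dict[str, dict[str, pd.Series]] = {}
    for name in term_names:
        tcols = _term_columns(df, schema, spec.term(name))
        per_term[name] = tcols
        for cname, s in tcols.items():
            cols[cname] = s
            origin[cname] = (name,)
    for a, b in spec.interactions:
        if a not in term_names or b not in term_names:
            continue
        for ca, sa in per_term[a].items():
            for cb, sb in per_term[b].items():
                cname = f"{ca}:{cb}"
                cols[cname] = sa * sb
                origin[cname] = (a, b)
    X = pd.DataFrame(cols, index=df.index)
    return X, origin


def fit_logistic_baseline(cohort: Cohort, spec: ModelSpec | None = None,
                          alpha: float = 0.05) -> FitReport:
    """Complete-case ML logistic fit with Wald inference and LR chi-square."""
    spec = spec or teddy_model_spec()
    schema = cohort.schema
    df = cohort.df
    term_names = [t.name for t in spec.terms]
    complete = ~df[term_names].isna().any(axis=1)
    dcc = df[complete]
    y = dcc[schema.outcome_name].to_numpy(dtype=float)
    X, origin = _design(dcc, schema, spec, term_names)
    n_params = X.shape[1] + 1
    if complete.sum() < n_params + 10:
        raise ValueError(
            f"only {int(complete.sum())} complete cases for {n_params} parameters")

    def _fit(design: pd.DataFrame):
        model = sm.Logit(y, sm.add_constant(design, has_constant="add"))
        try:
            res = model.fit(disp=0, maxiter=100)
        except Exception as exc:  # includes PerfectSeparationError
            raise SeparationError(f"logistic fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", True):
            raise SeparationError("logistic fit did not converge")
        return res

    # blockwise entry: log-likelihood after each cumulative block
    block_ll: list[float] = []
    if spec.blocks:
        entered: list[str] = []
        for blk in spec.blocks:
            entered.extend(blk)
            Xb, _ = _design(dcc, schema, spec, entered)
            block_ll.append(float(_fit(Xb).llf))

    res = _fit(X)
    params = res.params
    big = params.drop(labels=["const"], errors="ignore").abs()
    if (big > 30).any():
        raise SeparationError(
            f"separation suspected: coefficient for {big.idxmax()!r} diverges")
    z = stats.norm.ppf(1 - alpha / 2)
    est, se = params, res.bse
    rows = []
    for name in params.index:
        e, s = float(est[name]), float(se[name])
        rows.append({
            "term": "Intercept" if name == "const" else name,
            "estimate": e, "se": s,
            "p_value": float(res.pvalues[name]),
            "OR": float(np.exp(e)),
            "ci_low": float(np.exp(e - z * s)),
            "ci_high": float(np.exp(e + z * s)),
        })
    table = pd.DataFrame(rows)
    chi2 = float(2 * (res.llf - res.llnull))
    dof = int(res.df_model)
    p_model = float(stats.chi2.sf(chi2, dof))
    acc = float(np.mean((res.predict() >= 0.5) == y))
    return FitReport(table, chi2, dof, p_model, acc, int(complete.sum()),
                     tuple(block_ll), dict(origin))


def compare_with_rules(report: FitReport, rules, alpha: float = 0.05) -> pd.DataFrame:
    """Per-covariate concordance between regression and selected rules.

    A covariate is "in regression" when any of its design terms
    (dummies or interactions) has p < alpha, and "in rules" when it
    appears in >= 1 selected rule.  Flags covariates picked up by one
    method only.
    """
    sig: set[str] = set()
    for _, row in report.table.iterrows():
        if row["term"] == "Intercept":
            continue
        if row["p_value"] < alpha:
            sig.update(report.term_covariates.get(row["term"], ()))
    rule_feats: set[str] = set()
    for r in rules:
        rule_feats.update(r.features)
    rows = []
    for cov in sorted(sig | rule_feats):
        in_reg, in_rule = cov in sig, cov in rule_feats
        category = ("both" if in_reg and in_rule
                    else "regression-only" if in_reg else "rule-only")
        rows.append({"covariate": cov, "significant_in_regression": in_reg,
                     "in_rules": in_rule, "category": category})
    return pd.DataFrame(rows, columns=["covariate", "significant_in_regression",
                                       "in_rules", "category"])
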