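"""Synthetic cohort generation with planted rule effects.

The generator emulates the statistical structure the downstream
analysis assumes: covariates drawn independently from declared
marginals, a Bernoulli outcome whose log-odds are a baseline plus the
summed log-odds increments of the *planted rules* a record endorses,
and covariate missingness applied after the outcome is drawn.

Planted rules are evaluated against the clean (pre-masking) covariate
values, with one exception: the derived missing-data count is computed
from the missingness masks themselves, so planted rules conditioning on
it are meaningful.  Masking therefore never alters the outcome vector
except through that explicit channel.

:func:`teddy_like_spec` provides a ready-made specification whose
marginals follow the published descriptive table of the TEDDY
first-year withdrawal sample (country, maternal age, smoking, alcohol,
employment, dad participation, risk-perception accuracy, state-anxiety
score) and whose planted rules default to the eight published
withdrawal-risk rules.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit, logit

from .cohort import Cohort, CovariateSchema, Variable
from .rules import Rule, load_teddy_rules, parse_rule, rule_to_text

__all__ = [
    "CategoricalMarginal",
    "TruncNormalMarginal",
    "PoissonMarginal",
    "CountMarginal",
    "SyntheticSpec",
    "RuleTruth",
    "PlantedTruth",
    "generate_cohort",
    "generate_with_truth",
    "planted_truth",
    "teddy_like_spec",
    "teddy_schema",
    "spec_to_yaml",
    "spec_from_yaml",
]

MISSING_COUNT_NAME = "n_missing"


# ---------------------------------------------------------------------------
# marginal distributions


@dataclass(frozen=True)
class CategoricalMarginal:
    levels: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
        p = tuple(float(x) for x in self.probs)
        object.__setattr__(self, "probs", p)
        if len(p) != len(self.levels):
            raise ValueError("levels and probs must align")
        if any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("categorical probabilities must be >= 0 and sum to 1")

    kind = "categorical"

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(np.asarray(self.levels, dtype=object), size=n, p=self.probs)

    def prob_in(self, subset) -> float:
        return sum(p for l, p in zip(self.levels, self.probs) if l in subset)


@dataclass(frozen=True)
class TruncNormalMarginal:
    """Normal(mean, sd) truncated to [lo, hi]."""

    mean: float
    sd: float
    lo: float = -math.inf
    hi: float = math.inf

    kind = "continuous"

    def _dist(self):
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self._dist().rvs(size=n, random_state=rng)

    def cdf(self, x: float) -> float:
        return float(self._dist().cdf(x))

    def prob_less(self, t: float) -> float:
        return self.cdf(t)


@dataclass(frozen=True)
class PoissonMarginal:
    """Poisson(mean), optionally capped (values above ``cap`` collapse to it)."""

    mean: float
    cap: int | None = None

    kind = "count"

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        v = rng.poisson(self.mean, size=n)
        if self.cap is not None:
            v = np.minimum(v, self.cap)
        return v.astype(float)

    def prob_less(self, t: float) -> float:
        """P(X < t) on the capped support."""
        k = math.ceil(t) - 1  # largest integer < t
        if k < 0:
            return 0.0
        if self.cap is not None and k >= self.cap:
            return 1.0
        return float(stats.poisson(self.mean).cdf(k))


@dataclass(frozen=True)
class CountMarginal:
    """Explicit pmf on a finite set of non-negative integers."""

    values: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        v = tuple(int(x) for x in self.values)
        p = tuple(float(x) for x in self.probs)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "probs", p)
        if len(v) != len(p) or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("invalid count pmf")

    kind = "count"

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(np.asarray(self.values), size=n, p=self.probs).astype(float)

    def prob_less(self, t: float) -> float:
        return sum(p for v, p in zip(self.values, self.probs) if v < t)


# ---------------------------------------------------------------------------
# spec


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic cohort draw.

    ``baseline_logit`` is the log-odds of withdrawal for a record that
    endorses no planted rule; each planted rule a record endorses adds
    its log-odds ``effect`` (effects are additive on the logit scale).
    ``missingness`` maps covariate names to independent per-cell missing
    probabilities.
    """

    n: int
    marginals: Mapping[str, object]
    baseline_logit: float
    planted_rules: tuple[tuple[Rule, float], ...] = ()
    missingness: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    outcome_name: str = "withdrawn"

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        object.__setattr__(self, "marginals", dict(self.marginals))
        object.__setattr__(self, "missingness", dict(self.missingness))
        object.__setattr__(self, "planted_rules",
                           tuple((r, float(e)) for r, e in self.planted_rules))
        for name, p in self.missingness.items():
            if name not in self.marginals:
                raise ValueError(f"missingness on unknown covariate {name!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missing probability for {name!r} outside [0, 1]")
        known = set(self.marginals) | {MISSING_COUNT_NAME}
        for rule, _ in self.planted_rules:
            unknown = set(rule.features) - known
            if unknown:
                raise ValueError(f"planted rule uses unknown feature(s) {sorted(unknown)}")

    @property
    def schema(self) -> CovariateSchema:
        variables = []
        for name, m in self.marginals.items():
            if m.kind == "categorical":
                variables.append(Variable(name, "categorical", levels=m.levels))
            elif m.kind == "continuous":
                lo = m.lo if math.isfinite(m.lo) else None
                hi = m.hi if math.isfinite(m.hi) else None
                variables.append(Variable(name, "continuous", lo=lo, hi=hi))
            else:
                variables.append(Variable(name, "count", lo=0))
        variables.append(Variable(MISSING_COUNT_NAME, "count", lo=0, derived=True))
        return CovariateSchema(tuple(variables), self.outcome_name)


# ---------------------------------------------------------------------------
# generation


def _draw(spec: SyntheticSpec):
    """Deterministic draw of (clean covariates, masks, truth frame, logit, outcome)."""
    ss = np.random.SeedSequence(spec.seed)
    cov_ss, mask_ss, out_ss = ss.spawn(3)
    cov_rng = np.random.default_rng(cov_ss)
    mask_rng = np.random.default_rng(mask_ss)
    out_rng = np.random.default_rng(out_ss)
    n = spec.n

    clean = pd.DataFrame(
        {name: m.sample(cov_rng, n) for name, m in spec.marginals.items()})
    masks = {}
    for name in spec.marginals:
        p = spec.missingness.get(name, 0.0)
        if p > 0:
            masks[name] = mask_rng.random(n) < p
    n_missing = np.zeros(n, dtype=float)
    for m in masks.values():
        n_missing += m

    truth = clean.copy()
    truth[MISSING_COUNT_NAME] = n_missing
    eta = np.full(n, spec.baseline_logit)
    endorse = np.zeros((n, len(spec.planted_rules)), dtype=bool)
    for k, (rule, effect) in enumerate(spec.planted_rules):
        e = rule.endorsement(truth)
        endorse[:, k] = e
        eta += effect * e
    p_withdraw = expit(eta)
    y = (out_rng.random(n) < p_withdraw).astype(np.int64)
    return clean, masks, truth, p_withdraw, endorse, y


def generate_with_truth(spec: SyntheticSpec):
    """Generate a cohort plus the generation-time ground truth.

    Returns ``(cohort, truth_df, endorse, p_withdraw)`` where
    ``truth_df`` holds the clean covariates plus the missing count,
    ``endorse`` the n x (number of planted rules) endorsement matrix
    used when drawing the outcome, and ``p_withdraw`` the per-record
    withdrawal probability.
    """
    clean, masks, truth, p_withdraw, endorse, y = _draw(spec)
    observed = clean.copy()
    for name, mask in masks.items():
        col = observed[name]
        if spec.marginals[name].kind == "categorical":
            observed[name] = col.where(~mask, other=np.nan)
        else:
            vals = col.to_numpy(dtype=float).copy()
            vals[mask] = np.nan
            observed[name] = vals
    observed[spec.outcome_name] = y
    cohort = Cohort(spec.schema, observed)
    return cohort, truth, endorse, p_withdraw


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Draw one cohort; fully reproducible from ``spec.seed``."""
    return generate_with_truth(spec)[0]


# ---------------------------------------------------------------------------
# planted truth


@dataclass(frozen=True)
class RuleTruth:
    rule: Rule
    effect: float
    endorsement_prob: float
    expected_rate: float
    method: str  # "analytic" | "mc"


@dataclass(frozen=True)
class PlantedTruth:
    overall_rate: float
    overall_method: str
    rules: tuple[RuleTruth, ...]


def _missing_count_pmf(spec: SyntheticSpec) -> CountMarginal:
    """Poisson-binomial pmf of the missing-data count (independent masks)."""
    pmf = np.array([1.0])
    for name in spec.marginals:
        p = spec.missingness.get(name, 0.0)
        if p > 0:
            pmf = np.convolve(pmf, [1 - p, p])
    return CountMarginal(tuple(range(len(pmf))), tuple(pmf))


def _condition_prob(cond, spec: SyntheticSpec, nm_pmf: CountMarginal) -> float:
    m = nm_pmf if cond.feature == MISSING_COUNT_NAME else spec.marginals[cond.feature]
    if cond.op == "in":
        return m.prob_in(cond.value)
    less = m.prob_less(cond.value)
    return less if cond.op == "<" else 1.0 - less

def _endorsement_prob(rule: Rule, spec: SyntheticSpec, nm_pmf: CountMarginal) -> float:
    simplified = rule.simplify()
    if simplified is None:
        return 0.0
    prob = 1.0
    for f in simplified.features:
        conds = [c for c in simplified.conditions if c.feature == f]
        if len(conds) == 1:
            prob *= _condition_prob(conds[0], spec, nm_pmf)
        else:  # numeric interval: lower and upper bound on the same feature
            lo = next(c.value for c in conds if c.op == ">=")
            hi = next(c.value for c in conds if c.op == "<")
            m = nm_pmf if f == MISSING_COUNT_NAME else spec.marginals[f]
            prob *= max(m.prob_less(hi) - m.prob_less(lo), 0.0)
    return prob


def planted_truth(spec: SyntheticSpec, mc_n: int = 200_000) -> PlantedTruth:
    """Expected endorsement probability and withdrawal rate per planted rule.

    Endorsement probabilities are analytic (covariates are independent
    by construction; conditions on the missing count use the exact
    Poisson-binomial pmf of the masks).  Conditional withdrawal rates
    are analytic — an exact enumeration over the other rules'
    endorsement indicators — when the planted rules condition on
    pairwise-disjoint feature sets; otherwise they are estimated by a
    Rao-Blackwellized Monte Carlo draw of ``mc_n`` records (averaging
    the exact per-record withdrawal probabilities over endorsers),
    flagged ``method="mc"``.
    """
    nm_pmf = _missing_count_pmf(spec)
    probs = [_endorsement_prob(r, spec, nm_pmf) for r, _ in spec.planted_rules]
    feats = [set(r.features) for r, _ in spec.planted_rules]
    disjoint = all(not (a & b) for a, b in combinations(feats, 2))

    if not spec.planted_rules:
        rate = float(expit(spec.baseline_logit))
        return PlantedTruth(rate, "analytic", ())

    if disjoint and len(spec.planted_rules) <= 14:
        effects = [e for _, e in spec.planted_rules]
        q = len(effects)
        rates, overall = [], 0.0
        # enumerate endorsement patterns of the independent rules
        pattern_rates = np.zeros(2 ** q)
        pattern_probs = np.zeros(2 ** q)
        for bits in range(2 ** q):
            pr, eta = 1.0, spec.baseline_logit
            for k in range(q):
                on = (bits >> k) & 1
                pr *= probs[k] if on else 1 - probs[k]
                eta += effects[k] * on
            pattern_probs[bits] = pr
            pattern_rates[bits] = expit(eta)
        overall = float(np.dot(pattern_probs, pattern_rates))
        truths = []
        for k, ((rule, effect), pk) in enumerate(zip(spec.planted_rules, probs)):
            if pk == 0:
                truths.append(RuleTruth(rule, effect, 0.0, float("nan"), "analytic"))
                continue
            on = np.array([(b >> k) & 1 for b in range(2 ** q)], dtype=bool)
            rate = float(np.dot(pattern_probs[on], pattern_rates[on]) / pk)
            truths.append(RuleTruth(rule, effect, pk, rate, "analytic"))
        return PlantedTruth(overall, "analytic", tuple(truths))

    mc_seed = int(np.random.SeedSequence([spec.seed, 0x7E0D]).generate_state(1)[0] % 2**31)
    mc_spec = dataclasses.replace(spec, n=mc_n, seed=mc_seed)
    _, _, endorse, p_withdraw = generate_with_truth(mc_spec)
    overall = float(p_withdraw.mean())
    truths = []
    for k, ((rule, effect), pk) in enumerate(zip(spec.planted_rules, probs)):
        sel = endorse[:, k]
        rate = float(p_withdraw[sel].mean()) if sel.any() else float("nan")
        truths.append(RuleTruth(rule, effect, pk, rate, "mc"))
    return PlantedTruth(overall, "mc", tuple(truths))


# ---------------------------------------------------------------------------
# the TEDDY-like default specification


def _teddy_marginals() -> dict:
    """Marginals following the published descriptive table of the study sample.

    Categorical probabilities are the printed counts among non-missing
    records; maternal age and anxiety follow the printed total-sample
    mean (SD), truncated to plausible instrument/biological ranges.
    The negative-life-events count has no printed marginal and uses a
    Poisson(1.5) capped at 10 — a typical stressful-life-events tally.
    """
    return {
        "country": CategoricalMarginal(
            ("Finland", "Germany", "Sweden", "United States"),
            (887 / 3757, 142 / 3757, 1283 / 3757, 1445 / 3757)),
        "sex": CategoricalMarginal(("male", "female"), (1890 / 3757, 1867 / 3757)),
        "maternal_age": TruncNormalMarginal(30.4, 5.2, 15.0, 50.0),
        "smoking": CategoricalMarginal(("no", "yes"), (3112 / 3579, 467 / 3579)),
        "alcohol_per_month": CountMarginal(
            (0, 1, 2, 3), (2968 / 3632, 273 / 3632, 273 / 3632, 118 / 3632)),
        "employment": CategoricalMarginal(("no", "yes"), (1843 / 3512, 1669 / 3512)),
        "dad_participation": CategoricalMarginal(("yes", "no"), (3437 / 3757, 320 / 3757)),
        "risk_perception": CategoricalMarginal(
            ("accurate", "underestimate"), (2164 / 3639, 1475 / 3639)),
        "anxiety_score": TruncNormalMarginal(39.1, 9.9, 20.0, 80.0),
        "negative_life_events": PoissonMarginal(1.5, cap=10),
    }


_TEDDY_MISSINGNESS = {
    "smoking": 178 / 3757,
    "alcohol_per_month": 125 / 3757,
    "employment": 245 / 3757,
    "risk_perception": 118 / 3757,
    "anxiety_score": 109 / 3757,
}


def teddy_schema() -> CovariateSchema:
    """The covariate schema of the TEDDY-like cohort (no data drawn)."""
    return SyntheticSpec(0, _teddy_marginals(), 0.0).schema


def teddy_like_spec(n: int, seed: int = 0, rule_effect: float = 1.0) -> SyntheticSpec:
    """Ready-made spec: published marginals, the eight fixture rules planted.

    The four risk-increasing rules get effect ``+rule_effect`` and the
    four risk-decreasing rules ``-rule_effect`` (log-odds).  The
    baseline log-odds is ``logit(0.2)``, the approximate first-year
    withdrawal rate of the study sample, defined for records endorsing
    no planted rule.
    """
    marginals = _teddy_marginals()
    base = SyntheticSpec(0, marginals, float(logit(0.2)),
                         missingness=_TEDDY_MISSINGNESS, seed=seed)
    rules = load_teddy_rules(base.schema)
    effects = [rule_effect] * 4 + [-rule_effect] * 4
    return dataclasses.replace(
        base, n=n, planted_rules=tuple(zip(rules, effects)))


# ---------------------------------------------------------------------------
# YAML round trip


def _marginal_to_dict(m) -> dict:
    if isinstance(m, CategoricalMarginal):
        return {"type": "categorical", "levels": list(m.levels), "probs": list(m.probs)}
    if isinstance(m, TruncNormalMarginal):
        return {"type": "truncnormal", "mean": m.mean, "sd": m.sd,
                "lo": None if not math.isfinite(m.lo) else m.lo,
                "hi": None if not math.isfinite(m.hi) else m.hi}
    if isinstance(m, PoissonMarginal):
        return {"type": "poisson", "mean": m.mean, "cap": m.cap}
    if isinstance(m, CountMarginal):
        return {"type": "count", "values": list(m.values), "probs": list(m.probs)}
    raise TypeError(f"unknown marginal {type(m).__name__}")


def _marginal_from_dict(d: dict):
    t = d["type"]
    if t == "categorical":
        return CategoricalMarginal(tuple(d["levels"]), tuple(d["probs"]))
    if t == "truncnormal":
        return TruncNormalMarginal(
            d["mean"], d["sd"],
            -math.inf if d.get("lo") is None else d["lo"],
            math.inf if d.get("hi") is None else d["hi"])
    if t == "poisson":
        return PoissonMarginal(d["mean"], d.get("cap"))
    if t == "count":
        return CountMarginal(tuple(d["values"]), tuple(d["probs"]))
    raise ValueError(f"unknown marginal type {t!r}")


def spec_to_yaml(spec: SyntheticSpec, path) -> None:
    schema = spec.schema
    d = {
        "n": spec.n,
        "seed": spec.seed,
        "baseline_logit": spec.baseline_logit,
        "outcome": spec.outcome_name,
        "marginals": {k: _marginal_to_dict(m) for k, m in spec.marginals.items()},
        "missingness": dict(spec.missingness),
        "planted_rules": [
            {"rule": rule_to_text(r, schema), "effect": e} for r, e in spec.planted_rules],
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False), "utf-8")


def spec_from_yaml(path) -> SyntheticSpec:
    d = yaml.safe_load(Path(path).read_text("utf-8"))
    marginals = {k: _marginal_from_dict(v) for k, v in d["marginals"].items()}
    base = SyntheticSpec(0, marginals, d["baseline_logit"],
                         missingness=d.get("missingness", {}),
                         seed=d.get("seed", 0),
                         outcome_name=d.get("outcome", "withdrawn"))
    schema = base.schema
    planted = tuple(
        (parse_rule(item["rule"], schema), float(item["effect"]))
        for item in d.get("planted_rules", []))
    return dataclasses.replace(base, n=d["n"], planted_rules=planted)
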