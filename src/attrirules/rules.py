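"""Conjunctive risk rules over cohort covariates.

A *rule* is a conjunction of conditions, each constraining a single
covariate: numeric covariates (continuous or count) through a half-open
threshold comparison (``x < t`` or ``x >= t``), categorical covariates
through membership in a proper subset of the declared levels.  A
participant *endorses* a rule when every condition holds for their
record; the endorsers form the rule's subgroup.

Missing values never endorse: a condition evaluated on a missing value
is false, so a record missing any conditioned covariate falls outside
the rule's subgroup.  This is deliberately conservative — a subgroup
defined by, say, "smoked during pregnancy" should not absorb records
whose smoking status is unknown.

Rules serialize to a human-readable one-line text form, e.g.::

    maternal_age < 27.5 AND country != Finland

and to JSON.  The eight withdrawal-risk rules reported for the TEDDY
first-year withdrawal analysis ship as a packaged fixture
(:func:`load_teddy_rules`).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import CovariateSchema

__all__ = [
    "RuleError",
    "Condition",
    "Rule",
    "condition_to_text",
    "rule_to_text",
    "parse_condition",
    "parse_rule",
    "load_rules_text",
    "dump_rules_text",
    "rule_to_dict",
    "rule_from_dict",
    "load_teddy_rules",
    "TEDDY_RULE_DIRECTIONS",
]

NUMERIC_OPS = ("<", ">=")


class RuleError(ValueError):
    """Malformed rule, condition, or rule text."""


@dataclass(frozen=True)
class Condition:
    """One covariate constraint.

    ``op`` is ``"<"`` or ``">="`` with a finite float ``value`` for
    numeric covariates, or ``"in"`` with a non-empty frozenset of level
    names for categorical covariates.
    """

    feature: str
    op: str
    value: object

    def __post_init__(self) -> None:
        if not self.feature or not isinstance(self.feature, str):
            raise RuleError("condition needs a non-empty feature name")
        if self.op in NUMERIC_OPS:
            v = float(self.value)
            if not math.isfinite(v):
                raise RuleError(f"non-finite threshold for {self.feature!r}")
            object.__setattr__(self, "value", v)
        elif self.op == "in":
            s = frozenset(str(x) for x in self.value)
            if not s:
                raise RuleError(f"empty level subset for {self.feature!r}")
            object.__setattr__(self, "value", s)
        else:
            raise RuleError(f"unknown comparator {self.op!r}")

    def evaluate(self, column: pd.Series) -> np.ndarray:
        """Vectorized truth value per record; missing evaluates False."""
        if self.op == "<":
            return (column < self.value).to_numpy(dtype=bool)
        if self.op == ">=":
            return (column >= self.value).to_numpy(dtype=bool)
        return column.isin(self.value).to_numpy(dtype=bool)

    def _key(self) -> tuple:
        if self.op == "in":
            return (self.feature, self.op, tuple(sorted(self.value)))
        return (self.feature, self.op, float(self.value))


@dataclass(frozen=True)
class Rule:
    """A conjunction of :class:`Condition` s.

    ``provenance`` optionally records ``(tree_id, node_id)`` for rules
    extracted from a tree ensemble.
    """

    conditions: tuple[Condition, ...]
    provenance: tuple[int, int] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        conds = tuple(self.conditions)
        if not conds:
            raise RuleError("a rule needs at least one condition")
        object.__setattr__(self, "conditions", conds)

    @property
    def features(self) -> tuple[str, ...]:
        """Distinct conditioned features, in first-appearance order."""
        seen: list[str] = []
        for c in self.conditions:
            if c.feature not in seen:
                seen.append(c.feature)
        return tuple(seen)

    def endorsement(self, df: pd.DataFrame) -> np.ndarray:
        """Boolean endorsement vector over the rows of ``df``."""
        out = np.ones(len(df), dtype=bool)
        for c in self.conditions:
            if c.feature not in df.columns:
                raise RuleError(f"rule references unknown feature {c.feature!r}")
            out &= c.evaluate(df[c.feature])
        return out

    def simplify(self) -> "Rule | None":
        """Merge conditions per feature into canonical form.

        Numeric conditions collapse to at most one lower (``>=``) and one
        upper (``<``) bound per feature; categorical subsets intersect.
        Returns ``None`` when the conjunction is unsatisfiable (empty
        interval or empty level subset).
        """
        lowers: dict[str, float] = {}
        uppers: dict[str, float] = {}
        subsets: dict[str, set] = {}
        order: list[str] = []
        for c in self.conditions:
            f = c.feature
            if f not in order:
                order.append(f)
            if c.op == ">=":
                lowers[f] = max(lowers.get(f, -math.inf), c.value)
            elif c.op == "<":
                uppers[f] = min(uppers.get(f, math.inf), c.value)
            else:
                subsets[f] = (subsets[f] & set(c.value)) if f in subsets else set(c.value)
        conds: list[Condition] = []
        for f in order:
            if f in subsets:
                if f in lowers or f in uppers:
                    raise RuleError(f"feature {f!r} mixes numeric and categorical conditions")
                if not subsets[f]:
                    return None
                conds.append(Condition(f, "in", frozenset(subsets[f])))
            else:
                lo = lowers.get(f)
                up = uppers.get(f)
                if lo is not None and up is not None and lo >= up:
                    return None
                if lo is not None:
                    conds.append(Condition(f, ">=", lo))
                if up is not None:
                    conds.append(Condition(f, "<", up))
        conds.sort(key=lambda c: (c.feature, c.op))
        return Rule(tuple(conds), self.provenance)

    def key(self) -> tuple:
        """Canonical identity (order-free, provenance-free)."""
        return tuple(sorted(c._key() for c in self.conditions))


# ---------------------------------------------------------------------------
# text serialization


def condition_to_text(cond: Condition, schema: "CovariateSchema | None" = None) -> str:
    if cond.op in NUMERIC_OPS:
        return f"{cond.feature} {cond.op} {cond.value:g}"
    levels = set(cond.value)
    if len(levels) == 1:
        return f"{cond.feature} == {next(iter(levels))}"
    if schema is not None:
        full = set(schema.variable(cond.feature).levels)
        if levels < full and len(full - levels) == 1:
            (excluded,) = full - levels
            return f"{cond.feature} != {excluded}"
    return f"{cond.feature} in {{{', '.join(sorted(levels))}}}"


def rule_to_text(rule: Rule, schema: "CovariateSchema | None" = None) -> str:
    return " AND ".join(condition_to_text(c, schema) for c in rule.conditions)


_COND_RE = re.compile(r"^\s*(\w+)\s*(<=|>=|==|!=|<|>|in)\s*(.+?)\s*$")


def parse_condition(text: str, schema: "CovariateSchema") -> Condition:
    m = _COND_RE.match(text)
    if not m:
        raise RuleError(f"cannot parse condition {text!r}")
    feature, op, rhs = m.groups()
    var = schema.variable(feature)  # raises SchemaError on unknown feature
    if var.kind in ("continuous", "count"):
        if op in ("==", "!=", "in"):
            raise RuleError(f"comparator {op!r} not valid for numeric feature {feature!r}")
        value = float(rhs)
        # canonicalize to the {<, >=} pair: on counts (integers) x > t means
        # x >= floor(t)+1 and x <= t means x < t+1; on continuous features
        # the boundary has probability zero and >= / < stand in directly.
        if op == ">":
            value = math.floor(value) + 1.0 if var.kind == "count" else value
            op = ">="
        elif op == "<=":
            value = math.floor(value) + 1.0 if var.kind == "count" else value
            op = "<"
        return Condition(feature, op, value)
    levels = set(var.levels)
    if op == "==":
        subset = {rhs}
    elif op == "!=":
        subset = levels - {rhs}
        if rhs not in levels:
            raise RuleError(f"unknown level {rhs!r} for {feature!r}")
    elif op == "in":
        subset = {s.strip() for s in rhs.strip().strip("{}").split(",") if s.strip()}
    else:
        raise RuleError(f"comparator {op!r} not valid for categorical feature {feature!r}")
    unknown = subset - levels
    if unknown:
        raise RuleError(f"unknown level(s) {sorted(unknown)} for {feature!r}")
    if not subset or subset == levels:
        raise RuleError(f"level subset for {feature!r} must be a non-empty proper subset")
    return Condition(feature, "in", frozenset(subset))


def parse_rule(text: str, schema: "CovariateSchema") -> Rule:
    parts = re.split(r"\s+AND\s+", text.strip())
    return Rule(tuple(parse_condition(p, schema) for p in parts))


def load_rules_text(path, schema: "CovariateSchema") -> list[Rule]:
    """Read one rule per line; blank lines and ``#`` comments ignored."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    return [parse_rule(line, schema) for line in lines
            if line.strip() and not line.lstrip().startswith("#")]


def dump_rules_text(rules: Iterable[Rule], schema: "CovariateSchema | None" = None) -> str:
    return "\n".join(rule_to_text(r, schema) for r in rules) + "\n"


# ---------------------------------------------------------------------------
# JSON serialization


def rule_to_dict(rule: Rule) -> dict:
    conds = []
    for c in rule.conditions:
        value = sorted(c.value) if c.op == "in" else c.value
        conds.append({"feature": c.feature, "op": c.op, "value": value})
    d: dict = {"conditions": conds}
    if rule.provenance is not None:
        d["provenance"] = list(rule.provenance)
    return d


def rule_from_dict(d: dict) -> Rule:
    conds = tuple(
        Condition(c["feature"], c["op"],
                  frozenset(c["value"]) if c["op"] == "in" else c["value"])
        for c in d["conditions"]
    )
    prov = tuple(d["provenance"]) if d.get("provenance") is not None else None
    return Rule(conds, prov)


# ---------------------------------------------------------------------------
# packaged fixture: the eight published withdrawal-risk rules

#: Direction labels printed alongside the eight fixture rules
#: (rules 1-4 risk-increasing, rules 5-8 risk-decreasing).
TEDDY_RULE_DIRECTIONS: tuple[str, ...] = ("increasing",) * 4 + ("decreasing",) * 4


def load_teddy_rules(schema: "CovariateSchema") -> list[Rule]:
    """The eight packaged withdrawal-risk rules, parsed against ``schema``.

    Use :func:`attrirules.synthetic.teddy_schema` for the matching
    covariate schema.
    """
    text = resources.files("attrirules").joinpath("data/teddy_rules.txt").read_text("utf-8")
    return [parse_rule(line, schema) for line in text.splitlines()
            if line.strip() and not line.lstrip().startswith("#")]
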