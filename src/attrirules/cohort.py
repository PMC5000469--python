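"""Cohort container, covariate schema, delimited I/O, and descriptive statistics.

The cohort is a participant-level table with one binary outcome column
(1 = withdrew from the study within the first year, 0 = remained
active) and mixed covariates: categorical (country, smoking, ...),
continuous (maternal age, anxiety score), and counts (negative life
events).  Missing covariate cells are allowed and are marked by NaN in
memory and by the empty string in files; the outcome is never missing.

The per-record number of missing covariate cells is itself materialized
as a *derived* count covariate (conventionally named ``n_missing``), so
rules and regression models may condition on it — missing-data burden
is a known predictor of study attrition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "SchemaError",
    "Variable",
    "CovariateSchema",
    "Cohort",
    "load_cohort",
    "write_cohort",
    "ContingencyCell",
    "withdrawal_rate",
    "crude_odds_ratio",
    "descriptive_table",
    "format_descriptive_markdown",
    "round_half_away",
]

KINDS = ("categorical", "continuous", "count")


class SchemaError(ValueError):
    """A value, column, or file violates the declared covariate schema."""


def round_half_away(x: float) -> int:
    """Round half away from zero (3.5 -> 4, -3.5 -> -4); used for percent display."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass(frozen=True)
class Variable:
    """One covariate declaration.

    ``levels`` are required for categorical variables (ordered, >= 2);
    ``lo``/``hi`` optionally bound numeric variables.  ``derived=True``
    marks a covariate recomputed from the others (the missing-data
    count) rather than read from files.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    lo: float | None = None
    hi: float | None = None
    derived: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for variable {self.name!r}")
        if self.kind == "categorical":
            if not self.levels or len(self.levels) < 2:
                raise SchemaError(f"categorical variable {self.name!r} needs >= 2 levels")
            object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
            if len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"duplicate levels in {self.name!r}")
        elif self.levels is not None:
            raise SchemaError(f"numeric variable {self.name!r} must not declare levels")

    @property
    def numeric(self) -> bool:
        return self.kind in ("continuous", "count")


@dataclass(frozen=True)
class CovariateSchema:
    variables: tuple[Variable, ...]
    outcome_name: str = "withdrawn"

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("variable names must be unique")
        if self.outcome_name in names:
            raise SchemaError("outcome must not collide with a covariate name")

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise SchemaError(f"unknown variable {name!r}")

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def observed_names(self) -> tuple[str, ...]:
        """Covariates read from files (i.e. not derived)."""
        return tuple(v.name for v in self.variables if not v.derived)

    @property
    def derived_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.derived)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out = []
        for v in self.variables:
            d: dict = {"name": v.name, "kind": v.kind}
            if v.levels is not None:
                d["levels"] = list(v.levels)
            if v.lo is not None:
                d["lo"] = v.lo
            if v.hi is not None:
                d["hi"] = v.hi
            if v.derived:
                d["derived"] = True
            out.append(d)
        return {"variables": out, "outcome": self.outcome_name}

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateSchema":
        variables = tuple(
            Variable(
                name=v["name"], kind=v["kind"],
                levels=tuple(v["levels"]) if v.get("levels") else None,
                lo=v.get("lo"), hi=v.get("hi"), derived=bool(v.get("derived", False)),
            )
            for v in d["variables"]
        )
        return cls(variables, d.get("outcome", "withdrawn"))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False), "utf-8")

    @classmethod
    def from_yaml(cls, path) -> "CovariateSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text("utf-8")))


class Cohort:
    """Schema-validated participant table.

    ``data`` must contain every non-derived covariate plus the outcome;
    derived missing-count covariates are (re)computed here, so they are
    always consistent with the actual missing cells.
    """

    def __init__(self, schema: CovariateSchema, data: pd.DataFrame, validate: bool = True):
        self.schema = schema
        df = data.reset_index(drop=True).copy()
        missing_cols = [c for c in (*schema.observed_names, schema.outcome_name)
                        if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"missing column(s): {missing_cols}")
        observed = list(schema.observed_names)
        for name in schema.derived_names:
            df[name] = df[observed].isna().sum(axis=1).astype(float)
        self._df = df[[*schema.covariate_names, schema.outcome_name]].copy()
        if validate:
            self._validate()
        for var in schema.variables:
            if var.numeric:
                self._df[var.name] = pd.to_numeric(self._df[var.name], errors="coerce")
        self._df[schema.outcome_name] = pd.to_numeric(
            self._df[schema.outcome_name]).astype(np.int64)

    def _validate(self) -> None:
        df, schema = self._df, self.schema
        y = df[schema.outcome_name]
        if y.isna().any():
            row = int(y.isna().idxmax())
            raise SchemaError(f"outcome {schema.outcome_name!r} missing at row {row}")
        bad = ~y.isin([0, 1])
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"outcome {schema.outcome_name!r} must be coded 0/1; "
                f"got {y.iloc[row]!r} at row {row}")
        for var in schema.variables:
            col = df[var.name]
            present = col.notna()
            if var.kind == "categorical":
                ok = col.isin(var.levels) | ~present
                if not ok.all():
                    row = int((~ok).idxmax())
                    raise SchemaError(
                        f"value {col.iloc[row]!r} at row {row} not a level of {var.name!r}")
            else:
                vals = pd.to_numeric(col, errors="coerce")
                bad = present & vals.isna()
                if bad.any():
                    row = int(bad.idxmax())
                    raise SchemaError(
                        f"non-numeric value {col.iloc[row]!r} at row {row} in {var.name!r}")
                if var.lo is not None and (vals < var.lo).any():
                    row = int((vals < var.lo).idxmax())
                    raise SchemaError(
                        f"value {vals.iloc[row]} below lower bound {var.lo} "
                        f"at row {row} in {var.name!r}")
                if var.hi is not None and (vals > var.hi).any():
                    row = int((vals > var.hi).idxmax())
                    raise SchemaError(
                        f"value {vals.iloc[row]} above upper bound {var.hi} "
                        f"at row {row} in {var.name!r}")
                if var.kind == "count" and ((vals.dropna() % 1) != 0).any():
                    raise SchemaError(f"count variable {var.name!r} has non-integer values")

    def __len__(self) -> int:
        return len(self._df)

    @property
    def n(self) -> int:
        return len(self._df)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def outcome(self) -> np.ndarray:
        return self._df[self.schema.outcome_name].to_numpy(dtype=np.int64)

    @property
    def missing_counts(self) -> np.ndarray:
        """Per-record count of missing (non-derived) covariate cells."""
        observed = list(self.schema.observed_names)
        return self._df[observed].isna().sum(axis=1).to_numpy(dtype=np.int64)


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def load_cohort(path, schema: CovariateSchema) -> Cohort:
    """Read a delimited cohort file (CSV by default, TSV by extension).

    Empty cells become missing values; derived missing-count covariates
    are recomputed rather than read, so a round trip through
    :func:`write_cohort` is exact.
    """
    try:
        raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    except OSError as exc:
        raise SchemaError(f"cannot read cohort file {path}: {exc}") from exc
    data: dict[str, pd.Series] = {}
    for name in (*schema.observed_names, schema.outcome_name):
        if name not in raw.columns:
            raise SchemaError(f"column {name!r} absent from {path}")
        col = raw[name].replace("", np.nan)
        var = None if name == schema.outcome_name else schema.variable(name)
        if var is None or var.numeric:
            vals = pd.to_numeric(col, errors="coerce")
            bad = col.notna() & vals.isna()
            if bad.any():
                row = int(bad.idxmax())
                raise SchemaError(f"non-numeric value {col.iloc[row]!r} "
                                  f"at row {row} in column {name!r}")
            data[name] = vals
        else:
            data[name] = col
    return Cohort(schema, pd.DataFrame(data))


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort (derived columns included) with empty-string missing cells."""
    df = cohort.df.copy()
    df[cohort.schema.outcome_name] = df[cohort.schema.outcome_name].astype(int)
    df.to_csv(path, sep=_sep_for(path), index=False, na_rep="")


# ---------------------------------------------------------------------------
# contingency-table statistics


@dataclass(frozen=True)
class ContingencyCell:
    """Active/withdrawn counts for one stratum of a covariate."""

    stratum_label: str
    n_active: int
    n_withdrawn: int

    def __post_init__(self) -> None:
        if self.n_active < 0 or self.n_withdrawn < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_active + self.n_withdrawn


def withdrawal_rate(cell: ContingencyCell) -> float:
    """Proportion withdrawn within the stratum: ``n_withdrawn / total``."""
    if cell.total == 0:
        raise ValueError(f"undefined withdrawal rate for empty stratum {cell.stratum_label!r}")
    return cell.n_withdrawn / cell.total


def crude_odds_ratio(
    exposed: ContingencyCell, unexposed: ContingencyCell, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Unadjusted odds ratio of withdrawal (exposed vs unexposed) with Wald CI.

    The CI uses the normal approximation on the log odds ratio with
    standard error ``sqrt(1/a + 1/b + 1/c + 1/d)``.  Zero cells raise:
    no continuity correction is applied silently.
    """
    a_e, w_e = exposed.n_active, exposed.n_withdrawn
    a_u, w_u = unexposed.n_active, unexposed.n_withdrawn
    if min(a_e, w_e, a_u, w_u) == 0:
        raise ValueError("crude_odds_ratio requires all four counts > 0 "
                         "(no continuity correction is applied)")
    or_ = (w_e * a_u) / (a_e * w_u)
    se = math.sqrt(1 / a_e + 1 / w_e + 1 / a_u + 1 / w_u)
    z = stats.norm.ppf(1 - alpha / 2)
    log_or = math.log(or_)
    return or_, (math.exp(log_or - z * se), math.exp(log_or + z * se))


# ---------------------------------------------------------------------------
# descriptive table (Actives / Withdrawals / Total)


def descriptive_table(cohort: Cohort) -> pd.DataFrame:
    """Per-variable summary stratified by outcome.

    Categorical and count-as-categorical rows report counts with
    row-normalized percents (share of the level's records that are
    active resp. withdrawn); continuous variables report mean and SD per
    stratum; every variable gets a ``(missing)`` row counting records
    with that cell missing.  Count variables are summarized as mean/SD
    plus the missing row.
    """
    if cohort.n == 0:
        raise ValueError("descriptive_table requires a non-empty cohort")
    df = cohort.df
    y = cohort.outcome.astype(bool)
    rows: list[dict] = []

    def add(variable: str, level: str, **kw) -> None:
        rows.append({"variable": variable, "level": level, **kw})

    for var in cohort.schema.variables:
        col = df[var.name]
        if var.kind == "categorical":
            for lev in var.levels:
                sel = (col == lev).to_numpy()
                na, nw = int((sel & ~y).sum()), int((sel & y).sum())
                tot = na + nw
                add(var.name, lev, n_active=na, n_withdrawn=nw, n_total=tot,
                    pct_active=100 * na / tot if tot else np.nan,
                    pct_withdrawn=100 * nw / tot if tot else np.nan)
        else:
            vals = col.to_numpy(dtype=float)
            for label, sel in (("active", ~y), ("withdrawn", y), ("total", np.ones_like(y))):
                sub = vals[sel.astype(bool) & ~np.isnan(vals)]
                add(var.name, f"mean_sd_{label}",
                    mean=float(np.mean(sub)) if sub.size else np.nan,
                    sd=float(np.std(sub, ddof=1)) if sub.size > 1 else np.nan,
                    n_total=int(sub.size))
        miss = col.isna().to_numpy()
        na, nw = int((miss & ~y).sum()), int((miss & y).sum())
        tot = na + nw
        add(var.name, "(missing)", n_active=na, n_withdrawn=nw, n_total=tot,
            pct_active=100 * na / tot if tot else np.nan,
            pct_withdrawn=100 * nw / tot if tot else np.nan)
    cols = ["variable", "level", "n_active", "pct_active", "n_withdrawn",
            "pct_withdrawn", "n_total", "mean", "sd"]
    out = pd.DataFrame(rows)
    for c in cols:
        if c not in out.columns:
            out[c] = np.nan
    return out[cols]


def format_descriptive_markdown(table: pd.DataFrame) -> str:
    """Human-readable markdown rendering with integer percents, e.g. ``296 (63%)``."""
    lines = ["| Variable | Level | Actives | Withdrawals | Total |",
             "|---|---|---|---|---|"]
    for _, r in table.iterrows():
        if isinstance(r["level"], str) and r["level"].startswith("mean_sd_"):
            if r["level"] == "mean_sd_active":
                lines.append(f"| {r['variable']} | M (SD) "
                             f"| {r['mean']:.1f} ({r['sd']:.1f}) |  |  |")
            continue
        if not np.isnan(r["n_total"]) and r["n_total"] > 0:
            pa, pw = round_half_away(r["pct_active"]), round_half_away(r["pct_withdrawn"])
            lines.append(f"| {r['variable']} | {r['level']} "
                         f"| {int(r['n_active'])} ({pa}%) "
                         f"| {int(r['n_withdrawn'])} ({pw}%) | {int(r['n_total'])} |")
        else:
            lines.append(f"| {r['variable']} | {r['level']} | 0 | 0 | 0 |")
    return "\n".join(lines) + "\n"
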