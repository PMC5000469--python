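"""Post-selection subgroup profiling: risk levels, coverage, redundancy.

Given the final rule set, this module reports the withdrawal rate of
each rule's subgroup against the overall cohort rate (with a
risk-increasing / risk-decreasing / neutral label), the fraction of the
population covered by no rule together with that group's withdrawal
rate, and the q x q redundancy matrix whose (i, j) entry is the
proportion of rule-i endorsers who also endorse rule j.

Rates for empty subgroups are flagged undefined (``None`` in profiles,
NaN in the matrix) rather than silently reported as zero.  CSV outputs
are the source of truth; the plots are conveniences.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cohort import Cohort
from .forest import endorsement_matrix
from .rules import Rule, rule_to_text

__all__ = [
    "SubgroupProfile",
    "CoverageReport",
    "RedundancyMatrix",
    "profile_rules",
    "redundancy_matrix",
    "render_reports",
]


@dataclass(frozen=True)
class SubgroupProfile:
    rule: Rule
    n_endorsing: int
    outcome_rate: float | None          # None when no record endorses
    direction: str                      # increasing | decreasing | neutral | undefined
    rate_ratio_vs_overall: float | None


@dataclass(frozen=True)
class CoverageReport:
    fraction_uncovered: float
    n_uncovered: int
    uncovered_outcome_rate: float | None


@dataclass(frozen=True)
class RedundancyMatrix:
    """Overlap proportions with the integer joint counts they derive from."""

    M: np.ndarray        # M[i, j] = joint[i, j] / counts[i]; NaN rows where counts[i] = 0
    counts: np.ndarray   # per-rule endorsement counts n_i
    joint: np.ndarray    # integer joint endorsement counts (symmetric)

    def check(self) -> None:
        """Exact integer invariants: unit diagonal and joint-count symmetry."""
        if not np.array_equal(self.joint, self.joint.T):
            raise AssertionError("joint endorsement counts are not symmetric")
        if not np.array_equal(np.diag(self.joint), self.counts):
            raise AssertionError("diagonal joint counts must equal endorsement counts")
        pos = self.counts > 0
        if not np.all(np.diag(self.M)[pos] == 1.0):
            raise AssertionError("diagonal overlap must be exactly 1 where n_i > 0")


def profile_rules(rules, cohort: Cohort):
    """Per-rule subgroup profile, overall rate, and coverage report.

    Returns ``(profiles, overall_rate, coverage)``.  Direction compares
    the subgroup rate with the overall cohort rate; an exact tie is
    labeled ``neutral`` and an empty subgroup ``undefined``.
    """
    rules = list(rules)
    y = cohort.outcome
    overall = float(y.mean()) if cohort.n else float("nan")
    E = endorsement_matrix(rules, cohort).astype(bool)
    profiles = []
    for k, rule in enumerate(rules):
        sel = E[:, k]
        ne = int(sel.sum())
        if ne == 0:
            profiles.append(SubgroupProfile(rule, 0, None, "undefined", None))
            continue
        rate = float(y[sel].mean())
        if rate > overall:
            direction = "increasing"
        elif rate < overall:
            direction = "decreasing"
        else:
            direction = "neutral"
        ratio = rate / overall if overall > 0 else None
        profiles.append(SubgroupProfile(rule, ne, rate, direction, ratio))
    covered = E.any(axis=1)
    n_unc = int((~covered).sum())
    unc_rate = float(y[~covered].mean()) if n_unc else None
    coverage = CoverageReport(n_unc / cohort.n if cohort.n else 0.0, n_unc, unc_rate)
    return profiles, overall, coverage


def redundancy_matrix(rules, cohort: Cohort) -> RedundancyMatrix:
    """Pairwise endorsement-overlap proportions for >= 1 rule."""
    rules = list(rules)
    if not rules:
        raise ValueError("redundancy_matrix needs at least one rule")
    E = endorsement_matrix(rules, cohort).astype(np.int64)
    joint = E.T @ E
    counts = np.diag(joint).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        M = joint / counts[:, None].astype(float)
    M[counts == 0, :] = np.nan
    # exact unit diagonal where defined (joint[ii] == counts[i])
    idx = np.flatnonzero(counts > 0)
    M[idx, idx] = 1.0
    return RedundancyMatrix(M, counts, joint)


def render_reports(profiles, matrix: RedundancyMatrix | None,
                   coverage: CoverageReport, overall_rate: float,
                   out_dir, schema=None, make_plots: bool = True) -> list[Path]:
    """Write profiles.csv, redundancy.csv, coverage.json (+ optional plots).

    Numbers in the files are the in-memory values, full precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    ppath = out / "profiles.csv"
    with open(ppath, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["rule", "n_endorsing", "outcome_rate", "direction",
                    "rate_ratio_vs_overall"])
        for p in profiles:
            w.writerow([rule_to_text(p.rule, schema), p.n_endorsing,
                        "" if p.outcome_rate is None else repr(p.outcome_rate),
                        p.direction,
                        "" if p.rate_ratio_vs_overall is None
                        else repr(p.rate_ratio_vs_overall)])
    written.append(ppath)

    rpath = out / "redundancy.csv"
    with open(rpath, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        q = 0 if matrix is None else matrix.M.shape[0]
        w.writerow(["rule_i"] + [f"rule_{j + 1}" for j in range(q)])
        if matrix is not None:
            for i in range(q):
                w.writerow([f"rule_{i + 1}"] + [repr(float(x)) for x in matrix.M[i]])
    written.append(rpath)

    cpath = out / "coverage.json"
    cpath.write_text(json.dumps({
        "overall_rate": overall_rate,
        "fraction_uncovered": coverage.fraction_uncovered,
        "n_uncovered": coverage.n_uncovered,
        "uncovered_outcome_rate": coverage.uncovered_outcome_rate,
    }, indent=2), "utf-8")
    written.append(cpath)

    if make_plots and profiles:
        written.extend(_plots(profiles, matrix, overall_rate, out))
    return written


def _plots(profiles, matrix, overall_rate, out: Path) -> list[Path]:
    from matplotlib.figure import Figure

    written = []
    fig = Figure(figsize=(max(6, 1.2 * len(profiles)), 4))
    ax = fig.add_subplot(111)
    xs = np.arange(len(profiles))
    rates = [p.outcome_rate if p.outcome_rate is not None else 0.0 for p in profiles]
    colors = ["#c0392b" if p.direction == "increasing" else "#2471a3" for p in profiles]
    ax.bar(xs, rates, color=colors)
    ax.axhline(overall_rate, color="k", ls="--", lw=1,
               label=f"overall ({overall_rate:.3f})")
    for x, p in zip(xs, profiles):
        ax.text(x, (p.outcome_rate or 0) + 0.005, f"n={p.n_endorsing}",
                ha="center", fontsize=8)
    ax.set_xticks(xs, [f"rule {i + 1}" for i in xs])
    ax.set_ylabel("withdrawal rate")
    ax.legend()
    path = out / "risk_levels.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    written.append(path)

    if matrix is not None:
        q = matrix.M.shape[0]
        fig = Figure(figsize=(1 + 0.6 * q, 1 + 0.6 * q))
        ax = fig.add_subplot(111)
        im = ax.imshow(matrix.M, vmin=0, vmax=1, cmap="Blues")
        for i in range(q):
            for j in range(q):
                v = matrix.M[i, j]
                if np.isfinite(v):
                    ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=7)
        ax.set_xlabel("also endorses rule j")
        ax.set_ylabel("endorsers of rule i")
        ax.set_xticks(range(q), [str(j + 1) for j in range(q)])
        ax.set_yticks(range(q), [str(i + 1) for i in range(q)])
        fig.colorbar(im, ax=ax, shrink=0.8)
        path = out / "redundancy.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        written.append(path)
    return written
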