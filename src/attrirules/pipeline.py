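"""End-to-end orchestration: cohort -> candidate rules -> pruning -> profiling.

A :class:`RunConfig` (YAML-loadable) names exactly one input source —
a cohort file with its schema, or a synthetic TEDDY-like cohort of a
given size — plus forest and pruning settings, the output directory,
and a single global seed.  The seed is expanded into independent
per-stage streams, so e.g. changing the forest size does not perturb
the synthetic cohort.

Every stage writes plain CSV/JSON outputs; the run ends with a
manifest recording the configuration, per-stage timings and record
counts (cohort n, pool q, selected rules, uncovered fraction), and a
SHA-256 checksum per output file.  Re-running an identical
configuration reproduces identical stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .baseline import compare_with_rules, fit_logistic_baseline, teddy_model_spec
from .cohort import Cohort, CovariateSchema, load_cohort, write_cohort
from .forest import ForestParams, extract_rules, grow_forest
from .profiling import profile_rules, redundancy_matrix, render_reports
from .pruning import PruneConfig, prune_rules
from .rules import TEDDY_RULE_DIRECTIONS, load_teddy_rules
from .synthetic import generate_cohort, planted_truth, teddy_like_spec

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "run_fixture_demo"]

log = logging.getLogger("attrirules")


@dataclass(frozen=True)
class RunConfig:
    out_dir: str
    seed: int = 0
    cohort_path: str | None = None
    schema_path: str | None = None
    synthetic_n: int | None = None
    forest: dict = field(default_factory=dict)       # ForestParams overrides
    prune: dict = field(default_factory=dict)        # PruneConfig overrides
    extraction_mode: str = "all_nodes"
    baseline: bool = True
    make_plots: bool = True
    log_level: str = "INFO"

    def validate(self) -> list[str]:
        """Collect every violation (empty list = valid)."""
        errors: list[str] = []
        sources = (self.cohort_path is not None) + (self.synthetic_n is not None)
        if sources != 1:
            errors.append("exactly one input source required: cohort_path or synthetic_n")
        if self.cohort_path is not None and self.schema_path is None:
            errors.append("cohort_path requires schema_path")
        if self.synthetic_n is not None and self.synthetic_n < 0:
            errors.append("synthetic_n must be >= 0")
        if self.extraction_mode not in ("all_nodes", "leaves"):
            errors.append(f"unknown extraction_mode {self.extraction_mode!r}")
        try:
            ForestParams(**{**self.forest, "seed": 0})
        except (TypeError, ValueError) as exc:
            errors.append(f"forest: {exc}")
        try:
            PruneConfig(**{**self.prune, "seed": 0})
        except (TypeError, ValueError) as exc:
            errors.append(f"prune: {exc}")
        if self.cohort_path is not None and self.schema_path is not None:
            try:
                schema = CovariateSchema.from_yaml(self.schema_path)
            except Exception as exc:
                errors.append(f"schema: {exc}")
            else:
                if not schema.covariate_names:
                    errors.append("schema declares no covariates")
        return errors

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict  # stage -> {"seconds": float, "outputs": {relpath: sha256}}
    counts: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2), "utf-8")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, idx: int) -> int:
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % 2**31)


class _StageRecorder:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.stages: dict = {}

    def record(self, name: str, t0: float, files) -> None:
        self.stages[name] = {
            "seconds": round(time.perf_counter() - t0, 4),
            "outputs": {str(Path(f).relative_to(self.out_dir)): _sha256(Path(f))
                        for f in files},
        }


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full flow; any stage failure aborts with partial outputs kept."""
    errors = config.validate()
    if errors:
        raise ValueError("invalid run config: " + "; ".join(errors))
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = _StageRecorder(out)
    counts: dict = {}

    # ---- input stage ------------------------------------------------------
    t0 = time.perf_counter()
    if config.synthetic_n is not None:
        spec = teddy_like_spec(config.synthetic_n, seed=_stage_seed(config.seed, 0))
        cohort = generate_cohort(spec)
        cpath = out / "cohort.csv"
        write_cohort(cohort, cpath)
        spath = out / "schema.yaml"
        cohort.schema.to_yaml(spath)
        files = [cpath, spath]
        rec.record("simulate", t0, files)
    else:
        schema = CovariateSchema.from_yaml(config.schema_path)
        cohort = load_cohort(config.cohort_path, schema)
        rec.record("load", t0, [])
    counts["n"] = cohort.n
    log.info("cohort: n=%d, withdrawal rate=%.3f", cohort.n,
             float(cohort.outcome.mean()) if cohort.n else float("nan"))

    # ---- rule generation --------------------------------------------------
    t0 = time.perf_counter()
    fp = ForestParams(**{**config.forest, "seed": _stage_seed(config.seed, 1)})
    forest = grow_forest(cohort, fp)
    pool = extract_rules(forest, mode=config.extraction_mode)
    pool_path = out / "rule_pool.txt"
    from .rules import dump_rules_text
    pool_path.write_text(dump_rules_text(pool.rules, cohort.schema), "utf-8")
    rec.record("discover", t0, [pool_path])
    counts["q_pool"] = pool.q
    log.info("rule generation: %d trees -> %d candidate rules", fp.n_trees, pool.q)

    # ---- pruning ----------------------------------------------------------
    t0 = time.perf_counter()
    pc = PruneConfig(**{**config.prune, "seed": _stage_seed(config.seed, 2)})
    model = prune_rules(pool, cohort, pc)
    mpath = out / "pruned_model.json"
    model.to_json(mpath, cohort.schema)
    rec.record("prune", t0, [mpath])
    counts["n_selected"] = len(model.selected)
    log.info("pruning: lambda*=%.5g -> %d selected rules",
             model.lambda_star, len(model.selected))

    # ---- profiling --------------------------------------------------------
    t0 = time.perf_counter()
    selected = list(model.rules)
    profiles, overall, coverage = profile_rules(selected, cohort)
    matrix = redundancy_matrix(selected, cohort) if selected else None
    files = render_reports(profiles, matrix, coverage, overall, out,
                           schema=cohort.schema, make_plots=config.make_plots)
    rec.record("profile", t0, files)
    counts["fraction_uncovered"] = coverage.fraction_uncovered
    log.info("profiling: overall rate=%.3f, uncovered=%.3f",
             overall, coverage.fraction_uncovered)

    # ---- baseline ---------------------------------------------------------
    if config.baseline:
        t0 = time.perf_counter()
        report = fit_logistic_baseline(cohort, teddy_model_spec())
        bpath = out / "baseline.csv"
        report.table.to_csv(bpath, index=False)
        comparison = compare_with_rules(report, selected)
        xpath = out / "comparison.csv"
        comparison.to_csv(xpath, index=False)
        rec.record("baseline", t0, [bpath, xpath])
        counts["baseline_n_used"] = report.n_used
        log.info("baseline: n_used=%d, model chi2=%.1f (df=%d), accuracy=%.3f",
                 report.n_used, report.chi2, report.df, report.accuracy)

    manifest = RunManifest(config.to_dict(), __version__, rec.stages, counts)
    manifest.to_json(out / "manifest.json")
    return manifest


def run_fixture_demo(out_dir, n: int = 10_000, seed: int = 0) -> RunManifest:
    """Fast demo: generate a TEDDY-like cohort and profile the packaged 8 rules.

    Skips rule learning entirely — the eight published rules are
    evaluated directly, producing the risk-level and redundancy reports.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = _StageRecorder(out)

    t0 = time.perf_counter()
    spec = teddy_like_spec(n, seed=_stage_seed(seed, 0))
    cohort = generate_cohort(spec)
    cpath = out / "cohort.csv"
    write_cohort(cohort, cpath)
    truth = planted_truth(spec, mc_n=100_000)
    tpath = out / "planted_truth.json"
    tpath.write_text(json.dumps({
        "overall_rate": truth.overall_rate,
        "method": truth.overall_method,
        "rules": [{"endorsement_prob": rt.endorsement_prob,
                   "expected_rate": rt.expected_rate,
                   "effect": rt.effect, "method": rt.method}
                  for rt in truth.rules]}, indent=2), "utf-8")
    rec.record("simulate", t0, [cpath, tpath])

    t0 = time.perf_counter()
    rules = load_teddy_rules(cohort.schema)
    profiles, overall, coverage = profile_rules(rules, cohort)
    matrix = redundancy_matrix(rules, cohort)
    files = render_reports(profiles, matrix, coverage, overall, out,
                           schema=cohort.schema, make_plots=True)
    rec.record("profile", t0, files)

    counts = {"n": cohort.n, "n_rules": len(rules),
              "fraction_uncovered": coverage.fraction_uncovered,
              "directions": list(TEDDY_RULE_DIRECTIONS)}
    manifest = RunManifest({"demo": True, "n": n, "seed": seed}, __version__,
                           rec.stages, counts)
    manifest.to_json(out / "manifest.json")
    return manifest
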