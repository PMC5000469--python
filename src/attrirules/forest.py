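"""Candidate-rule generation from bootstrapped recursive-partitioning trees.

Stage 1 of the pipeline.  Each tree is grown greedily on a bootstrap
resample of the cohort (with replacement, at full cohort size), using
binary splits that maximize the Gini impurity decrease of the binary
withdrawal outcome among a random feature subset drawn per split
(``ceil(sqrt(p))`` features by default).  Tree size is randomized: each
tree draws its leaf-count limit uniformly from ``{2, ..., max_leaves}``,
echoing rule-ensemble practice of harvesting rules from trees of varied
depth.  Numeric split thresholds sit at midpoints of adjacent observed
values; categorical splits are one-level-versus-rest, matching the form
of published withdrawal rules ("Finland = NO").

Every non-root node contributes a candidate rule — the conjunction of
the conditions on its root path — simplified and deduplicated across
the forest (a leaves-only mode is available).

Missing values: records missing the split feature are excluded from
that split's evaluation and are routed with the majority (larger)
child; when an extracted rule is later *evaluated*, a condition on a
missing value is false.  The two conventions coincide exactly on
complete data.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, SchemaError
from .rules import Condition, Rule

__all__ = [
    "ForestParams",
    "Node",
    "DecisionTree",
    "RulePool",
    "grow_tree",
    "grow_forest",
    "extract_rules",
    "endorsement_matrix",
]


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters.

    ``feature_fraction`` is the per-split fraction of features tried
    (``None`` means the classic ``ceil(sqrt(p))`` rule).
    """

    n_trees: int = 200
    max_leaves: int = 8
    min_leaf: int = 10
    feature_fraction: float | None = None
    feature_mode: str = "split"   # draw the subset per "split" or per "tree"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.max_leaves < 2:
            raise ValueError("max_leaves must be >= 2")
        if self.feature_fraction is not None and not 0 < self.feature_fraction <= 1:
            raise ValueError("feature_fraction must be in (0, 1]")
        if self.feature_mode not in ("split", "tree"):
            raise ValueError("feature_mode must be 'split' or 'tree'")

    def n_split_features(self, p: int) -> int:
        if self.feature_fraction is None:
            return max(1, math.ceil(math.sqrt(p)))
        return max(1, round(self.feature_fraction * p))


@dataclass
class Node:
    """Tree node; ``condition``/``condition_right`` describe the two children."""

    id: int
    n: int
    mean: float
    depth: int
    condition: Condition | None = None        # membership test of the left child
    condition_right: Condition | None = None  # complement, for path extraction
    missing_left: bool = False                # training routing of missing records
    left: "Node | None" = None
    right: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class DecisionTree:
    root: Node
    tree_id: int = 0

    def nodes(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            if not node.is_leaf:
                stack.extend([node.right, node.left])
        return out

    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes() if n.is_leaf)

    def route(self, df: pd.DataFrame) -> np.ndarray:
        """Leaf node id per record, honoring the training missing-value routing."""
        ids = np.empty(len(df), dtype=np.int64)
        stack = [(self.root, np.arange(len(df)))]
        while stack:
            node, idx = stack.pop()
            if node.is_leaf:
                ids[idx] = node.id
                continue
            col = df[node.condition.feature].iloc[idx]
            go_left = node.condition.evaluate(col)
            miss = col.isna().to_numpy()
            if node.missing_left:
                go_left = go_left | miss
            stack.append((node.left, idx[go_left]))
            stack.append((node.right, idx[~go_left]))
        return ids

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        by_id = {n.id: n.mean for n in self.nodes()}
        return np.array([by_id[i] for i in self.route(df)])


@dataclass(frozen=True)
class RulePool:
    """Deduplicated candidate rules."""

    rules: tuple[Rule, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        keys = [r.key() for r in self.rules]
        if len(set(keys)) != len(keys):
            raise ValueError("rule pool contains duplicates")

    @property
    def q(self) -> int:
        return len(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


# ---------------------------------------------------------------------------
# training-side feature store


class _Features:
    """Columnar view of a cohort for fast split search."""

    def __init__(self, cohort: Cohort):
        schema = cohort.schema
        self.names: list[str] = list(schema.covariate_names)
        self.kinds: list[str] = []
        self.arrays: list[np.ndarray] = []
        self.levels: list[tuple[str, ...] | None] = []
        for name in self.names:
            var = schema.variable(name)
            col = cohort.df[name]
            if var.kind == "categorical":
                codes = np.full(len(col), -1, dtype=np.int64)
                for i, lev in enumerate(var.levels):
                    codes[(col == lev).to_numpy()] = i
                self.arrays.append(codes)
                self.levels.append(var.levels)
                self.kinds.append("categorical")
            else:
                self.arrays.append(col.to_numpy(dtype=float))
                self.levels.append(None)
                self.kinds.append("numeric")
        self.p = len(self.names)


def _gini_decrease_numeric(v, yy, min_leaf):
    """Best midpoint split of sorted-by-value pairs; returns (gain, threshold) or None."""
    order = np.argsort(v, kind="stable")
    sv, sy = v[order], yy[order]
    m = sv.size
    cum = np.cumsum(sy)
    total = cum[-1]
    k = np.arange(1, m)  # left sizes
    distinct = sv[1:] > sv[:-1]
    ok = distinct & (k >= min_leaf) & (m - k >= min_leaf)
    if not ok.any():
        return None
    pos_l = cum[:-1]
    pos_r = total - pos_l
    # child impurity sums n_child * 2 p (1-p) = 2 * pos * (n - pos) / n
    child = 2 * pos_l * (k - pos_l) / k + 2 * pos_r * ((m - k) - pos_r) / (m - k)
    parent = 2 * total * (m - total) / m
    gains = np.where(ok, parent - child, -np.inf)
    best = int(np.argmax(gains))  # first maximum -> smallest threshold wins ties
    if gains[best] <= 1e-12:
        return None
    thr = (sv[best] + sv[best + 1]) / 2.0
    return float(gains[best]), thr


def _gini_decrease_categorical(codes, yy, n_levels, min_leaf):
    """Best one-level-vs-rest split; returns (gain, level_code) or None."""
    m = codes.size
    total = yy.sum()
    parent = 2 * total * (m - total) / m
    best = None
    counts = np.bincount(codes, minlength=n_levels)
    pos = np.bincount(codes, weights=yy, minlength=n_levels)
    for code in range(n_levels):  # level order -> deterministic tie-break
        nl = counts[code]
        nr = m - nl
        if nl < min_leaf or nr < min_leaf:
            continue
        pl, pr = pos[code], total - pos[code]
        child = 2 * pl * (nl - pl) / nl + 2 * pr * (nr - pr) / nr
        gain = parent - child
        if gain > 1e-12 and (best is None or gain > best[0]):
            best = (float(gain), code)
    return best


@dataclass
class _SplitChoice:
    gain: float
    feature_idx: int
    threshold: float | None
    level_code: int | None
    left_rows: np.ndarray
    right_rows: np.ndarray
    missing_left: bool


def _best_split(feats: _Features, y, rows, feat_indices, min_leaf) -> _SplitChoice | None:
    best: _SplitChoice | None = None
    for j in sorted(feat_indices):  # feature-index order -> deterministic tie-break
        arr = feats.arrays[j][rows]
        if feats.kinds[j] == "numeric":
            nm = ~np.isnan(arr)
            if nm.sum() < 2 * min_leaf:
                continue
            res = _gini_decrease_numeric(arr[nm], y[rows][nm], min_leaf)
            if res is None:
                continue
            gain, thr = res
            if best is None or gain > best.gain:
                go_left = arr < thr  # NaN compares False
                miss = ~nm
                left = rows[go_left]
                right = rows[~go_left & ~miss]
                missing_left = left.size >= right.size
                mrows = rows[miss]
                if missing_left:
                    left = np.concatenate([left, mrows])
                else:
                    right = np.concatenate([right, mrows])
                best = _SplitChoice(gain, j, thr, None, left, right, missing_left)
        else:
            nm = arr >= 0
            if nm.sum() < 2 * min_leaf:
                continue
            res = _gini_decrease_categorical(arr[nm], y[rows][nm].astype(float),
                                             len(feats.levels[j]), min_leaf)
            if res is None:
                continue
            gain, code = res
            if best is None or gain > best.gain:
                go_left = arr == code
                miss = ~nm
                left = rows[go_left]
                right = rows[~go_left & ~miss]
                missing_left = left.size >= right.size
                mrows = rows[miss]
                if missing_left:
                    left = np.concatenate([left, mrows])
                else:
                    right = np.concatenate([right, mrows])
                best = _SplitChoice(gain, j, None, code, left, right, missing_left)
    return best


def _split_conditions(feats: _Features, choice: _SplitChoice) -> tuple[Condition, Condition]:
    name = feats.names[choice.feature_idx]
    if choice.threshold is not None:
        return (Condition(name, "<", choice.threshold),
                Condition(name, ">=", choice.threshold))
    levels = feats.levels[choice.feature_idx]
    lev = levels[choice.level_code]
    rest = frozenset(levels) - {lev}
    return (Condition(name, "in", frozenset({lev})),
            Condition(name, "in", rest))


def _grow(feats: _Features, y: np.ndarray, params: ForestParams,
          rng: np.random.Generator, rows: np.ndarray, leaf_limit: int,
          tree_id: int, feature_pool: np.ndarray | None = None) -> DecisionTree:
    if feature_pool is None:
        feature_pool = np.arange(feats.p)
    counter = 0

    def make_node(node_rows, depth):
        nonlocal counter
        node = Node(id=counter, n=int(node_rows.size),
                    mean=float(y[node_rows].mean()), depth=depth)
        counter += 1
        return node

    def propose(node, node_rows):
        """Draw the split feature subset and find this node's best split."""
        if node_rows.size < 2 * params.min_leaf:
            return None
        mean = node.mean
        if mean == 0.0 or mean == 1.0:  # pure
            return None
        if params.feature_mode == "tree":
            feat_indices = feature_pool
        else:
            k = min(params.n_split_features(feats.p), feature_pool.size)
            feat_indices = rng.choice(feature_pool, size=k, replace=False)
        return _best_split(feats, y, node_rows, feat_indices, params.min_leaf)

    root = make_node(rows, 0)
    heap: list[tuple[float, int, Node, np.ndarray, _SplitChoice]] = []
    choice = propose(root, rows)
    if choice is not None:
        heapq.heappush(heap, (-choice.gain, root.id, root, rows, choice))
    n_leaves = 1
    while heap and n_leaves < leaf_limit:
        _, _, node, node_rows, choice = heapq.heappop(heap)
        cond_l, cond_r = _split_conditions(feats, choice)
        node.condition, node.condition_right = cond_l, cond_r
        node.missing_left = choice.missing_left
        node.left = make_node(choice.left_rows, node.depth + 1)
        node.right = make_node(choice.right_rows, node.depth + 1)
        n_leaves += 1
        for child, child_rows in ((node.left, choice.left_rows),
                                  (node.right, choice.right_rows)):
            child_choice = propose(child, child_rows)
            if child_choice is not None:
                heapq.heappush(heap, (-child_choice.gain, child.id, child,
                                      child_rows, child_choice))
    return DecisionTree(root, tree_id)


def grow_tree(cohort: Cohort, params: ForestParams,
              rng: np.random.Generator | int | None = None,
              leaf_limit: int | None = None) -> DecisionTree:
    """Grow one tree on the cohort itself (no bootstrap), fully seeded."""
    if cohort.n == 0:
        raise ValueError("cannot grow a tree on an empty cohort")
    rng = np.random.default_rng(params.seed if rng is None else rng)
    feats = _Features(cohort)
    y = cohort.outcome.astype(float)
    rows = np.arange(cohort.n)
    return _grow(feats, y, params, rng, rows,
                 params.max_leaves if leaf_limit is None else leaf_limit, 0)


def grow_forest(cohort: Cohort, params: ForestParams) -> list[DecisionTree]:
    """Grow ``n_trees`` trees on independent bootstrap resamples.

    Per-tree randomness comes from spawned child streams of a single
    seed sequence, so the forest is reproducible regardless of how the
    work is scheduled.  Each tree draws its leaf-count limit uniformly
    from ``{2, ..., max_leaves}``.
    """
    if cohort.n == 0:
        raise ValueError("cannot grow a forest on an empty cohort")
    feats = _Features(cohort)
    y = cohort.outcome.astype(float)
    n = cohort.n
    trees = []
    for t, child in enumerate(np.random.SeedSequence(params.seed).spawn(params.n_trees)):
        rng = np.random.default_rng(child)
        rows = rng.integers(0, n, size=n)
        leaf_limit = int(rng.integers(2, params.max_leaves + 1))
        pool = None
        if params.feature_mode == "tree":
            k = params.n_split_features(feats.p)
            pool = np.sort(rng.choice(feats.p, size=min(k, feats.p), replace=False))
        trees.append(_grow(feats, y, params, rng, rows, leaf_limit, t, pool))
    return trees


def extract_rules(forest: list[DecisionTree], mode: str = "all_nodes") -> RulePool:
    """Harvest candidate rules from every tree's paths.

    ``mode="all_nodes"`` (default) takes one rule per non-root node;
    ``mode="leaves"`` restricts to leaf nodes.  Rules are simplified
    (intervals merged per feature), unsatisfiable conjunctions dropped,
    and duplicates removed across the whole forest (first provenance
    kept).  Single-leaf trees contribute nothing.
    """
    if mode not in ("all_nodes", "leaves"):
        raise ValueError(f"unknown extraction mode {mode!r}")
    if not forest:
        raise ValueError("empty forest")
    seen: dict[tuple, Rule] = {}
    for tree in forest:
        stack: list[tuple[Node, tuple[Condition, ...]]] = [(tree.root, ())]
        while stack:
            node, path = stack.pop()
            if path and (mode == "all_nodes" or node.is_leaf):
                rule = Rule(path, provenance=(tree.tree_id, node.id)).simplify()
                if rule is not None and rule.key() not in seen:
                    seen[rule.key()] = rule
            if not node.is_leaf:
                stack.append((node.left, path + (node.condition,)))
                stack.append((node.right, path + (node.condition_right,)))
    return RulePool(tuple(seen.values()))


def endorsement_matrix(pool, cohort: Cohort) -> np.ndarray:
    """n x q binary matrix: entry (i, k) = 1 iff record i endorses rule k.

    Conditions on missing values evaluate false, so records missing a
    conditioned covariate never endorse.
    """
    rules = list(pool)
    for rule in rules:
        for f in rule.features:
            cohort.schema.variable(f)  # raises SchemaError on unknown feature
    M = np.zeros((cohort.n, len(rules)), dtype=np.uint8)
    for k, rule in enumerate(rules):
        M[:, k] = rule.endorsement(cohort.df)
    return M
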