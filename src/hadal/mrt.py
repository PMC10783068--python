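"""Multivariate regression trees for community-environment relationships.

A multivariate regression tree (De'ath-style) recursively splits the
samples on environmental thresholds so as to minimise the within-node
sum of squared Euclidean distances of community rows to their node
centroid.  Candidate thresholds are midpoints of adjacent observed
predictor values; the explained variance of a split is
(SS_parent - SS_left - SS_right) / SS_total.  Tree size is chosen by
k-fold cross-validation of the relative error (optionally with the
1-SE rule).  By default the community matrix is Hellinger-transformed
(square root of relative abundance), the standard choice for Euclidean
partitioning of count data.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class MrtNode:
    node_id: int
    sample_idx: np.ndarray  # row indices of samples in this node
    ss: float  # within-node SS around the centroid
    depth: int
    predictor: str | None = None  # split variable (None for a leaf)
    threshold: float | None = None  # go left if x <= threshold
    gain: float = 0.0  # SS_parent - SS_left - SS_right
    left: "MrtNode | None" = None
    right: "MrtNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.predictor is None


@dataclass
class MrtModel:
    root: MrtNode
    ss_total: float
    predictors: list[str]
    sample_ids: list[str]
    cv_table: pd.DataFrame  # size, cv_relative_error, se
    chosen_size: int
    transform: str
    splits: list[MrtNode] = field(default_factory=list)  # in growth order

    def explained_variance(self) -> float:
        """Total explained variance of the pruned tree, percent of SS_total."""
        if self.ss_total == 0:
            return 0.0
        return 100.0 * sum(s.gain for s in self.splits) / self.ss_total

    def leaves(self) -> list[MrtNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.left, node.right])
        return out


def hellinger(y: np.ndarray) -> np.ndarray:
    """Square root of row-wise relative abundances."""
    sums = y.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return np.sqrt(y / sums)


def _node_ss(y: np.ndarray, idx: np.ndarray) -> float:
    sub = y[idx]
    centroid = sub.mean(axis=0)
    return float(((sub - centroid) ** 2).sum())


def _best_split(y, x_frame, idx, min_leaf):
    """Exhaustive best split of one node over all predictor midpoints.

    Ties in gain break by (predictor name, threshold) lexicographic
    order so fits are deterministic.
    """
    parent_ss = _node_ss(y, idx)
    best = None  # (gain, predictor, threshold, left_idx, right_idx)
    for name in x_frame.columns:
        x = x_frame[name].to_numpy(dtype=float)[idx]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        distinct = np.flatnonzero(np.diff(xs) > 0)
        for cut in distinct:
            thr = (xs[cut] + xs[cut + 1]) / 2.0
            left = idx[order[: cut + 1]]
            right = idx[order[cut + 1 :]]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            gain = parent_ss - _node_ss(y, left) - _node_ss(y, right)
            key = (-gain, name, thr)
            if best is None or key < best[0]:
                best = (key, name, thr, left, right, gain)
    return best


def _grow(y, x_frame, min_leaf, max_depth, max_leaves):
    """Best-first greedy growth; returns (root, splits in growth order)."""
    counter = [0]

    def make_node(idx, depth):
        node = MrtNode(counter[0], idx, _node_ss(y, idx), depth)
        counter[0] += 1
        return node

    root = make_node(np.arange(len(y)), 0)
    heap = []

    def push(node):
        if node.depth >= max_depth or len(node.sample_idx) < 2 * min_leaf:
            return
        if node.ss <= 1e-12:
            return
        best = _best_split(y, x_frame, node.sample_idx, min_leaf)
        if best is None or best[5] <= 1e-12:
            return
        heapq.heappush(heap, (best[0], node.node_id, node, best))

    push(root)
    splits = []
    while heap and len(splits) + 1 < max_leaves:
        _, _, node, best = heapq.heappop(heap)
        _, name, thr, left, right, gain = best
        node.predictor = name
        node.threshold = float(thr)
        node.gain = float(gain)
        node.left = make_node(left, node.depth + 1)
        node.right = make_node(right, node.depth + 1)
        splits.append(node)
        push(node.left)
        push(node.right)
    return root, splits


def fit_mrt(
    y: pd.DataFrame,
    x: pd.DataFrame,
    cv_folds: int = 10,
    seed: int | None = None,
    transform: str = "hellinger",
    min_leaf: int = 2,
    max_depth: int = 6,
    one_se: bool = False,
) -> MrtModel:
    """Fit a multivariate regression tree of community ``y`` on predictors ``x``.

    ``y``: samples x taxa counts or abundances; ``x``: samples x numeric
    predictors (constant predictors are dropped with a warning).  The
    tree is grown greedily and pruned back to the size minimising the
    cross-validated relative error.
    """
    if len(y) != len(x):
        raise ValueError("y and x must have the same samples")
    if len(y) < 8:
        raise ValueError("need >= 8 samples to fit an MRT")
    if transform not in ("hellinger", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    x = x.apply(pd.to_numeric, errors="coerce")
    keep = []
    for name in x.columns:
        col = x[name]
        if col.isna().any():
            raise ValueError(f"predictor {name!r} has missing/non-numeric values")
        if col.nunique() < 2:
            logger.warning("dropping constant predictor %r", name)
            continue
        keep.append(name)
    if not keep:
        raise ValueError("no usable (non-constant numeric) predictors")
    x = x[keep]
    y_mat = y.to_numpy(dtype=float)
    if transform == "hellinger":
        y_mat = hellinger(y_mat)
    ss_total = _node_ss(y_mat, np.arange(len(y_mat)))
    max_leaves = max(len(y_mat) // min_leaf, 1)
    root, splits = _grow(y_mat, x, min_leaf, max_depth, max_leaves)
    max_size = len(splits) + 1

    # cross-validated relative error for every nested tree size
    n = len(y_mat)
    rng = np.random.default_rng(seed)
    folds = min(cv_folds, n)
    assignment = rng.permutation(np.arange(n) % folds)
    cv_err = np.zeros((folds, max_size))
    for f in range(folds):
        test = np.flatnonzero(assignment == f)
        train = np.flatnonzero(assignment != f)
        sub_x = x.iloc[train].reset_index(drop=True)
        sub_root, sub_splits = _grow(
            y_mat[train], sub_x, min_leaf, max_depth, max_leaves
        )
        # map original test rows through the fold's tree
        for size in range(1, max_size + 1):
            used = sub_splits[: size - 1]
            preds = _fold_predict(y_mat[train], sub_root, used, x, test)
            cv_err[f, size - 1] = float(((y_mat[test] - preds) ** 2).sum())
    totals = cv_err.sum(axis=0)
    rel = totals / ss_total if ss_total > 0 else np.ones(max_size)
    se = cv_err.std(axis=0, ddof=1) * np.sqrt(folds) / ss_total if ss_total > 0 else np.zeros(max_size)
    cv_table = pd.DataFrame(
        {"size": np.arange(1, max_size + 1), "cv_relative_error": rel, "se": se}
    )
    best_idx = int(np.argmin(rel))
    if one_se:
        cutoff = rel[best_idx] + se[best_idx]
        best_idx = int(np.argmax(rel <= cutoff))
    chosen_size = best_idx + 1

    # prune: keep only the first chosen_size - 1 splits of the growth order
    kept = splits[: chosen_size - 1]
    for node in splits[chosen_size - 1 :]:
        node.predictor = None
        node.threshold = None
        node.gain = 0.0
        node.left = None
        node.right = None
    return MrtModel(
        root=root,
        ss_total=ss_total,
        predictors=keep,
        sample_ids=[str(s) for s in y.index],
        cv_table=cv_table,
        chosen_size=chosen_size,
        transform=transform,
        splits=kept,
    )


def _fold_predict(y_train, root, splits_used, x_frame, test_rows):
    active = {id(s) for s in splits_used}
    preds = np.empty((len(test_rows), y_train.shape[1]))
    for k, row in enumerate(test_rows):
        node = root
        while not node.is_leaf and id(node) in active:
            val = float(x_frame.iloc[row][node.predictor])
            node = node.left if val <= node.threshold else node.right
        preds[k] = y_train[node.sample_idx].mean(axis=0)
    return preds


def variance_decomposition(model: MrtModel) -> dict[str, float]:
    """Explained variance (percent of total SS) summed per split predictor."""
    out: dict[str, float] = {}
    if model.ss_total == 0:
        return out
    for node in model.splits:
        pct = 100.0 * node.gain / model.ss_total
        out[node.predictor] = out.get(node.predictor, 0.0) + pct
    return out
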