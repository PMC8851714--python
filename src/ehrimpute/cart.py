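"""Classification and regression trees with donor-leaf sampling.

This is the conditional model used inside the chained-equations engine
and the base learner of the validation forest.  Binary recursive
partitioning, greedy best split over candidate predictors; split score
is variance (SSE) reduction for a continuous target and Gini impurity
decrease for a categorical one.  Determinism: ties in split score are
broken by the first predictor in column order, then by the smaller
threshold; leaf-class ties by the smaller class code.

Categorical predictors are handled by ordering their levels by the mean
(or positive-class rate) of the target and treating the ordered codes as
ordinal — the classical reduction of the optimal subset-vs-rest split.
Missing predictor values are routed, at prediction time, to the child
that received more training rows.

Every leaf keeps the indices of the training rows it contains, so a
missing cell dropped into a leaf can be imputed by a uniform *donor
draw* from the observed target values in that leaf (preserving the
target's conditional spread, unlike a leaf-mean prediction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numba as nb
import numpy as np
import pandas as pd

from .data_model import ConfigError

__all__ = ["TreeControls", "Tree", "fit_cart", "grow_tree", "encode_frame"]


@dataclass(frozen=True)
class TreeControls:
    max_depth: int = 5
    min_leaf_size: int = 5


@nb.njit(cache=True)
def _best_split_reg(X, y, rows, cols, min_leaf):  # pragma: no cover - numba
    n = rows.size
    s = 0.0
    s2 = 0.0
    for i in range(n):
        v = y[rows[i]]
        s += v
        s2 += v * v
    parent = s2 - s * s / n
    best_gain = 1e-12
    best_col = -1
    best_thr = 0.0
    xv = np.empty(n)
    for ci in range(cols.size):
        c = cols[ci]
        for i in range(n):
            xv[i] = X[rows[i], c]
        order = np.argsort(xv)
        sl = 0.0
        sl2 = 0.0
        for i in range(n - 1):
            v = y[rows[order[i]]]
            sl += v
            sl2 += v * v
            if xv[order[i]] == xv[order[i + 1]]:
                continue
            nl = i + 1
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            sr = s - sl
            sr2 = s2 - sl2
            child = (sl2 - sl * sl / nl) + (sr2 - sr * sr / nr)
            gain = parent - child
            if gain > best_gain:
                best_gain = gain
                best_col = c
                best_thr = 0.5 * (xv[order[i]] + xv[order[i + 1]])
    return best_col, best_thr, best_gain


@nb.njit(cache=True)
def _best_split_gini(X, y, rows, cols, min_leaf, k):  # pragma: no cover - numba
    n = rows.size
    cnt = np.zeros(k)
    for i in range(n):
        cnt[int(y[rows[i]])] += 1.0
    sq = 0.0
    for j in range(k):
        sq += cnt[j] * cnt[j]
    parent = n - sq / n  # n * gini
    best_gain = 1e-12
    best_col = -1
    best_thr = 0.0
    xv = np.empty(n)
    cl = np.empty(k)
    for ci in range(cols.size):
        c = cols[ci]
        for i in range(n):
            xv[i] = X[rows[i], c]
        order = np.argsort(xv)
        for j in range(k):
            cl[j] = 0.0
        for i in range(n - 1):
            cl[int(y[rows[order[i]]])] += 1.0
            if xv[order[i]] == xv[order[i + 1]]:
                continue
            nl = i + 1
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            sql = 0.0
            sqr = 0.0
            for j in range(k):
                sql += cl[j] * cl[j]
                d = cnt[j] - cl[j]
                sqr += d * d
            child = (nl - sql / nl) + (nr - sqr / nr)
            gain = parent - child
            if gain > best_gain:
                best_gain = gain
                best_col = c
                best_thr = 0.5 * (xv[order[i]] + xv[order[i + 1]])
    return best_col, best_thr, best_gain


@nb.njit(cache=True)
def _apply(feature, threshold, left, right, nan_left, X):  # pragma: no cover
    out = np.empty(X.shape[0], dtype=np.int64)
    for i in range(X.shape[0]):
        node = 0
        while feature[node] >= 0:
            v = X[i, feature[node]]
            if np.isnan(v):
                node = left[node] if nan_left[node] else right[node]
            elif v <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = node
    return out


class Tree:
    """A fitted CART; arrays indexed by node id, root = 0."""

    def __init__(self, feature, threshold, left, right, nan_left, value,
                 leaf_rows, importances, is_classifier, n_classes):
        self.feature = feature
        self.threshold = threshold
        self.left = left
        self.right = right
        self.nan_left = nan_left
        self.value = value            # leaf prediction (mean or class code)
        self.leaf_rows = leaf_rows    # node id -> training row indices
        self.importances = importances
        self.is_classifier = is_classifier
        self.n_classes = n_classes

    @property
    def n_leaves(self) -> int:
        return int((self.feature < 0).sum())

    @property
    def depth(self) -> int:
        d = np.zeros(self.feature.size, dtype=int)
        for node in range(self.feature.size):
            if self.feature[node] >= 0:
                d[self.left[node]] = d[node] + 1
                d[self.right[node]] = d[node] + 1
        return int(d.max())

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf node id for each row of X (NaN routed to the larger child)."""
        return _apply(self.feature, self.threshold, self.left, self.right,
                      self.nan_left, np.ascontiguousarray(X, dtype=np.float64))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.value[self.apply(X)]

    def donor_draw(self, X: np.ndarray, y_fit: np.ndarray, rng) -> np.ndarray:
        """Impute each row of X with a uniform draw from its leaf's donors."""
        leaves = self.apply(X)
        out = np.empty(leaves.size, dtype=float)
        for i, leaf in enumerate(leaves):
            donors = self.leaf_rows[int(leaf)]
            out[i] = y_fit[donors[rng.integers(donors.size)]]
        return out


def grow_tree(X: np.ndarray, y: np.ndarray, controls: TreeControls,
              is_classifier: bool, n_classes: int = 0,
              rows: np.ndarray | None = None, mtry: int | None = None,
              rng=None) -> Tree:
    """Grow a tree on the float matrix ``X`` (fit rows must be NaN-free).

    ``mtry`` < p enables per-split uniform feature subsampling (for
    forests); it requires ``rng``.  ``rows`` restricts fitting to a row
    subset (bootstrap samples may repeat rows).
    """
    n, p = X.shape
    if rows is None:
        rows = np.arange(n, dtype=np.int64)
    rows = np.asarray(rows, dtype=np.int64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    X = np.ascontiguousarray(X, dtype=np.float64)
    all_cols = np.arange(p, dtype=np.int64)

    feature, threshold, left, right, nan_left, value = [], [], [], [], [], []
    leaf_rows = {}
    importances = np.zeros(p)

    def leaf_value(idx):
        if is_classifier:
            cnt = np.bincount(y[idx].astype(np.int64), minlength=n_classes)
            return float(cnt.argmax())  # tie -> smaller code
        return float(y[idx].mean())

    # stack of (row indices, depth, parent slot, is_left_child)
    stack = [(rows, 0, -1, False)]
    while stack:
        idx, depth, parent, is_left = stack.pop()
        node = len(feature)
        if parent >= 0:
            if is_left:
                left[parent] = node
            else:
                right[parent] = node
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        nan_left.append(False)
        value.append(0.0)

        yv = y[idx]
        pure = (np.all(yv == yv[0]) if yv.size else True)
        col = -1
        if not pure and depth < controls.max_depth and idx.size >= 2 * controls.min_leaf_size:
            if mtry is not None and mtry < p:
                cols = np.sort(rng.choice(p, size=mtry, replace=False)).astype(np.int64)
            else:
                cols = all_cols
            if is_classifier:
                col, thr, gain = _best_split_gini(X, y, idx, cols,
                                                 controls.min_leaf_size, n_classes)
            else:
                col, thr, gain = _best_split_reg(X, y, idx, cols,
                                                controls.min_leaf_size)
        if col < 0:
            value[node] = leaf_value(idx)
            leaf_rows[node] = idx
            continue
        go_left = X[idx, col] <= thr
        feature[node] = col
        threshold[node] = thr
        nan_left[node] = bool(go_left.sum() >= (~go_left).sum())
        importances[col] += gain
        # push right first so the left child gets the next node id
        stack.append((idx[~go_left], depth + 1, node, False))
        stack.append((idx[go_left], depth + 1, node, True))

    return Tree(np.array(feature, dtype=np.int64),
                np.array(threshold, dtype=np.float64),
                np.array(left, dtype=np.int64),
                np.array(right, dtype=np.int64),
                np.array(nan_left, dtype=bool),
                np.array(value, dtype=np.float64),
                leaf_rows, importances, is_classifier, n_classes)


# ---------------------------------------------------------------------------
# pandas-facing encoding

def _order_levels_by_target(codes: np.ndarray, y: np.ndarray, n_levels: int,
                            positive: np.ndarray | None) -> np.ndarray:
    """Rank of each level when sorted by mean target (ties: original code)."""
    obs = ~np.isnan(codes)
    c = codes[obs].astype(np.int64)
    t = positive[obs] if positive is not None else y[obs]
    sums = np.bincount(c, weights=t, minlength=n_levels)
    cnts = np.bincount(c, minlength=n_levels).astype(float)
    means = np.where(cnts > 0, sums / np.maximum(cnts, 1.0), np.inf)
    order = np.lexsort((np.arange(n_levels), means))
    rank = np.empty(n_levels)
    rank[order] = np.arange(n_levels, dtype=float)
    return rank


def encode_frame(predictors: pd.DataFrame, kinds: dict) -> tuple:
    """Encode a mixed frame as (float matrix, per-column level lists).

    Continuous columns pass through; binary map no→0 / yes→1;
    categorical columns become level codes (level list sorted for
    determinism) — target-aware ordering happens inside :func:`fit_cart`.
    """
    cols, levels = [], {}
    for j, name in enumerate(predictors.columns):
        kind = kinds[name]
        col = predictors[name]
        if kind == "continuous":
            cols.append(col.to_numpy(dtype=float))
        elif kind == "binary":
            cols.append(col.map({"no": 0.0, "yes": 1.0}).to_numpy(dtype=float))
            levels[j] = ["no", "yes"]
        elif kind == "categorical":
            levs = sorted(col.dropna().unique())
            mapping = {v: float(i) for i, v in enumerate(levs)}
            cols.append(col.map(mapping).to_numpy(dtype=float))
            levels[j] = levs
        else:
            raise ConfigError(f"variable {name!r} of kind {kind!r} cannot enter a tree")
    X = np.column_stack(cols) if cols else np.empty((len(predictors), 0))
    return X, levels


def fit_cart(target: pd.Series, predictors: pd.DataFrame, kinds: dict,
             controls: TreeControls = TreeControls()) -> tuple:
    """Fit a CART of ``target`` on ``predictors`` (all rows used, no NaN in X).

    ``kinds`` maps every column (and the target name) to its semantic
    kind.  Returns ``(tree, X_encoded, y_encoded, target_levels)`` where
    ``target_levels`` decodes class codes back to labels (None for a
    regression tree).
    """
    X, cat_levels = encode_frame(predictors, kinds)
    tkind = kinds[target.name]
    if tkind == "continuous":
        y = target.to_numpy(dtype=float)
        is_clf, k, tlevels = False, 0, None
        positive = None
    else:
        tlevels = (["no", "yes"] if tkind == "binary"
                   else sorted(target.dropna().unique()))
        mapping = {v: float(i) for i, v in enumerate(tlevels)}
        y = target.map(mapping).to_numpy(dtype=float)
        is_clf, k = True, len(tlevels)
        positive = (y == k - 1).astype(float) if k == 2 else y
    # order categorical-predictor levels by mean target, then treat as ordinal
    for j in cat_levels:
        n_lev = len(cat_levels[j])
        if n_lev > 2:
            rank = _order_levels_by_target(X[:, j], y, n_lev, positive)
            obs = ~np.isnan(X[:, j])
            X[obs, j] = rank[X[obs, j].astype(np.int64)]
    tree = grow_tree(X, y, controls, is_classifier=is_clf, n_classes=k)
    return tree, X, y, tlevels
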