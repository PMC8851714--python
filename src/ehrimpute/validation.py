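"""Held-out classifier validation of an imputed table.

After imputation, the usefulness of the filled values is checked by
predicting a binary outcome (insurance enrollment in the motivating
application) with a random forest — bagged CART trees with per-split
feature subsampling — trained on 80% of the rows where the target is
observed and scored on the held-out 20%.  Imputed *feature* values may
be used freely; imputed target values are never scored.  Reported:
accuracy, F1 on the positive (rare) class, the confusion matrix and
mean-impurity-decrease feature importances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cart import TreeControls, _order_levels_by_target, encode_frame, grow_tree
from .data_model import DataError

__all__ = ["ForestConfig", "ValidationResult", "validate"]


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 200
    max_depth: int = 12
    min_leaf_size: int = 5
    mtry: int | None = None  # default ceil(sqrt(p))


@dataclass
class ValidationResult:
    accuracy: float
    f1: float
    confusion: dict            # tp / tn / fp / fn, positive class = "yes"
    importances: dict
    n_train: int
    n_test: int
    seed: int
    predictions: pd.Series = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "f1": self.f1,
                "confusion": self.confusion, "importances": self.importances,
                "n_train": self.n_train, "n_test": self.n_test, "seed": self.seed}


def binary_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple:
    """(accuracy, f1, confusion) for 0/1 arrays, positive class = 1.

    F1 is defined as 0 when precision + recall is 0.
    """
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n if n else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, f1, {"tp": tp, "tn": tn, "fp": fp, "fn": fn}


def validate(table, target: str, features, split: float = 0.8, seed: int = 0,
             forest: ForestConfig = ForestConfig(),
             observed_mask: pd.Series | None = None,
             group_by_patient: bool = False) -> ValidationResult:
    """Train/test a random forest for ``target`` on ``features``.

    ``table`` is a visit-level (or patient-level) table; rows enter only
    where the target is observed (optionally further restricted by
    ``observed_mask``, e.g. to visits where the target was observed
    *before* imputation).  ``group_by_patient`` keeps all visits of a
    patient on the same side of the split (leakage-aware alternative to
    the default row-level split).
    """
    df = table.df
    if table.kinds.get(target) != "binary":
        raise DataError(f"validation target {target!r} must be binary")
    for f in features:
        if f not in df.columns:
            raise DataError(f"feature {f!r} not in table")
        if df[f].isna().all():
            raise DataError(f"feature {f!r} is fully missing")

    keep = df[target].notna()
    if observed_mask is not None:
        keep &= observed_mask.reindex(df.index, fill_value=False)
    sub = df.loc[keep]
    y = (sub[target] == "yes").to_numpy(dtype=float)

    kinds = {f: table.kinds[f] for f in features}
    X, cat_levels = encode_frame(sub[features], kinds)
    n = len(sub)
    if n < 10:
        raise DataError("too few target-observed rows to split")

    rng = np.random.default_rng(seed)
    if group_by_patient:
        pats = sub[table.id_col].to_numpy()
        uniq = pd.unique(pats)
        perm = rng.permutation(len(uniq))
        n_tr_p = int(math.floor(split * len(uniq)))
        train_pats = set(uniq[perm[:n_tr_p]])
        train_idx = np.flatnonzero(np.isin(pats, list(train_pats)))
        test_idx = np.flatnonzero(~np.isin(pats, list(train_pats)))
    else:
        perm = rng.permutation(n)
        n_tr = int(math.floor(split * n))
        train_idx, test_idx = perm[:n_tr], perm[n_tr:]
    if train_idx.size == 0 or test_idx.size == 0:
        raise DataError("degenerate train/test split")

    # order categorical-feature levels by positive rate on the training rows
    for j, levs in cat_levels.items():
        if len(levs) > 2:
            rank = _order_levels_by_target(X[train_idx, j], y[train_idx],
                                           len(levs), y[train_idx])
            obs = ~np.isnan(X[:, j])
            X[obs, j] = rank[X[obs, j].astype(np.int64)]

    p = X.shape[1]
    mtry = forest.mtry or max(1, math.ceil(math.sqrt(p)))
    controls = TreeControls(max_depth=forest.max_depth,
                            min_leaf_size=forest.min_leaf_size)
    # drop NaN-feature rows from fitting (split search needs complete rows);
    # test rows with NaN are still scored via majority-side routing
    fit_ok = train_idx[~np.isnan(X[train_idx]).any(axis=1)]
    if fit_ok.size == 0:
        raise DataError("no complete-feature training rows")

    seeds = np.random.SeedSequence(seed).spawn(forest.n_trees)
    votes = np.zeros(test_idx.size)
    importances = np.zeros(p)
    for s in seeds:
        trng = np.random.default_rng(s)
        boot = fit_ok[trng.integers(fit_ok.size, size=fit_ok.size)]
        tree = grow_tree(X, y, controls, is_classifier=True, n_classes=2,
                         rows=boot, mtry=mtry, rng=trng)
        votes += tree.value[tree.apply(X[test_idx])]
        importances += tree.importances
    y_pred = (votes * 2 > forest.n_trees).astype(float)  # tie -> negative class
    acc, f1, conf = binary_metrics(y[test_idx], y_pred)

    total = importances.sum()
    imp = {f: float(importances[j] / total) if total else 0.0
           for j, f in enumerate(features)}
    preds = pd.Series(np.where(y_pred == 1, "yes", "no"),
                      index=sub.index[test_idx])
    return ValidationResult(accuracy=acc, f1=f1, confusion=conf, importances=imp,
                            n_train=int(train_idx.size), n_test=int(test_idx.size),
                            seed=seed, predictions=preds)
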