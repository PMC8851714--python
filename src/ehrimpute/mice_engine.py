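"""Multiple imputation by chained equations with CART conditional models.

Operates on the patient-level table (one randomly chosen visit per
patient).  The engine creates ``m`` copies of the data, initializes
every missing cell with a uniformly random placeholder drawn from the
variable's observed values, then for a fixed number of sweeps visits the
variables in order of increasing missingness and, for each, refits a
tree of that variable on all other variables using the rows where it was
originally observed and redraws each missing cell from a uniform donor
among the observed values in the cell's terminal leaf.  Finally the m
completed copies are pooled by selecting, per missing cell (default) or
per copy, one of the m candidate values uniformly at random.

Donor draws keep every imputed value inside the variable's observed
support (levels for categorical, observed range for continuous) and
preserve conditional spread, unlike leaf-mean prediction.  Date
variables never enter the engine — tree models mangle them — and are
handled downstream by carry-forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cart import Tree, TreeControls, _order_levels_by_target, fit_cart, grow_tree  # noqa: F401
from .data_model import DataError, PatientTable

__all__ = ["MiceConfig", "ImputedPatientTable", "mice_impute", "fit_cart"]

POOLING = ("per_cell_random", "per_copy_random")


@dataclass(frozen=True)
class MiceConfig:
    m: int = 5                      # completed data copies
    iterations: int = 5             # chained-equation sweeps per copy
    max_depth: int = 5
    min_leaf_size: int = 5
    seed: int = 0
    pooling: str = "per_cell_random"

    def __post_init__(self):
        if self.m < 1 or self.iterations < 1:
            raise ValueError("m and iterations must be >= 1")
        if self.pooling not in POOLING:
            raise ValueError(f"pooling must be one of {POOLING}")

    @property
    def tree_controls(self) -> TreeControls:
        return TreeControls(max_depth=self.max_depth,
                            min_leaf_size=self.min_leaf_size)


@dataclass
class ImputedPatientTable:
    """Completed patient table plus audit information.

    ``imputed_mask`` flags the cells that were filled; ``candidates``
    retains, per variable, the m candidate values for each imputed cell
    (diagnostics); ``trace`` logs the per-sweep mean of imputed values
    per (copy, variable) as a convergence diagnostic.
    """

    table: PatientTable
    imputed_mask: pd.DataFrame
    candidates: dict = field(default_factory=dict)
    trace: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def _column_codec(col: pd.Series, kind: str):
    """(encode -> float array with NaN, levels or None)."""
    if kind == "continuous":
        return col.to_numpy(dtype=float), None
    if kind == "binary":
        levels = ["no", "yes"]
    else:
        levels = sorted(col.dropna().unique())
    mapping = {v: float(i) for i, v in enumerate(levels)}
    return col.map(mapping).to_numpy(dtype=float), levels


def mice_impute(table: PatientTable, specs, config: MiceConfig) -> ImputedPatientTable:
    """Chained-equations imputation of the patient-level table.

    Eligible variables are those whose spec includes the ``mice`` stage
    (binary / categorical / continuous).  Variables with zero observed
    values cannot be modeled: they are left missing, excluded from the
    predictor matrix and reported in ``warnings``.  Deterministic under
    ``config.seed``.
    """
    if len(table.df) < 2:
        raise DataError("chained-equations imputation needs at least two patients "
                        "(no donors in a single-row table)")
    spec_by_name = {s.name: s for s in specs}
    eligible = [s.name for s in specs
                if s.eligible("mice") and s.kind != "date" and s.name in table.df.columns]

    warnings = []
    usable, codes, levels = [], [], {}
    for name in eligible:
        col = table.df[name]
        if col.notna().sum() == 0:
            warnings.append(f"{name}: no observed values at patient level; left missing")
            continue
        enc, lev = _column_codec(col, spec_by_name[name].kind)
        usable.append(name)
        codes.append(enc)
        if lev is not None:
            levels[len(codes) - 1] = lev

    out = table.copy()
    n = len(table.df)
    if not usable:
        mask = pd.DataFrame(False, index=table.df.index, columns=table.variables)
        return ImputedPatientTable(out, mask, warnings=warnings)

    M = np.column_stack(codes)  # (n, q) float, NaN = missing
    q = M.shape[1]
    kinds = [spec_by_name[name].kind for name in usable]
    miss = np.isnan(M)
    if not miss.any():
        mask = pd.DataFrame(False, index=table.df.index, columns=table.variables)
        return ImputedPatientTable(out, mask, warnings=warnings)

    # visit order: increasing missingness fraction, ties by column order
    frac = miss.mean(axis=0)
    visit = sorted((j for j in range(q) if miss[:, j].any()),
                   key=lambda j: (frac[j], j))
    obs_rows = {j: np.flatnonzero(~miss[:, j]) for j in range(q)}
    miss_rows = {j: np.flatnonzero(miss[:, j]) for j in visit}

    children = np.random.SeedSequence(config.seed).spawn(config.m + 1)
    pool_rng = np.random.default_rng(children[-1])

    finals = []
    trace = {}
    for copy_i in range(config.m):
        rng = np.random.default_rng(children[copy_i])
        work = M.copy()
        for j in visit:  # random placeholders from observed values
            donors = M[obs_rows[j], j]
            work[miss_rows[j], j] = donors[rng.integers(donors.size,
                                                        size=miss_rows[j].size)]
        for it in range(config.iterations):
            for j in visit:
                fit_rows = obs_rows[j]
                other = [c for c in range(q) if c != j]
                Xe = work[:, other].copy()
                y = work[:, j]
                # target-aware ordinal encoding of multi-level categorical predictors
                for pos, c in enumerate(other):
                    lev = levels.get(c)
                    if lev is not None and len(lev) > 2:
                        if kinds[j] == "continuous":
                            positive = None
                        else:
                            k_t = len(levels[j])
                            positive = ((y == k_t - 1).astype(float)
                                        if k_t == 2 else y)
                        rank = _order_levels_by_target(
                            Xe[fit_rows, pos], y[fit_rows], len(lev),
                            positive[fit_rows] if positive is not None else None)
                        Xe[:, pos] = rank[Xe[:, pos].astype(np.int64)]
                is_clf = kinds[j] != "continuous"
                k = len(levels[j]) if is_clf else 0
                tree = grow_tree(Xe, y, config.tree_controls, is_classifier=is_clf,
                                 n_classes=k, rows=fit_rows)
                work[miss_rows[j], j] = tree.donor_draw(Xe[miss_rows[j]], y, rng)
                trace.setdefault((copy_i, usable[j]), []).append(
                    float(work[miss_rows[j], j].mean()))
        finals.append(work)

    stacked = np.stack(finals)  # (m, n, q)
    pooled = M.copy()
    if config.pooling == "per_copy_random":
        pooled = stacked[pool_rng.integers(config.m)].copy()
    else:
        for j in visit:
            pick = pool_rng.integers(config.m, size=miss_rows[j].size)
            pooled[miss_rows[j], j] = stacked[pick, miss_rows[j], j]
    pooled[~miss] = M[~miss]  # observed cells conserved bit-exactly

    candidates = {usable[j]: (miss_rows[j].copy(),
                              stacked[:, miss_rows[j], j].T.copy())
                  for j in visit}

    # decode back into the pandas frame
    for j, name in enumerate(usable):
        rows = miss_rows.get(j)
        if rows is None:
            continue
        lev = levels.get(j)
        if lev is None:
            col = out.df[name].to_numpy(dtype=float, copy=True)
            col[rows] = pooled[rows, j]
            out.df[name] = col
        else:
            filled = out.df[name].copy()
            filled.iloc[rows] = [lev[int(v)] for v in pooled[rows, j]]
            out.df[name] = filled

    mask = pd.DataFrame(False, index=table.df.index, columns=table.variables)
    for j in visit:
        mask.iloc[miss_rows[j], mask.columns.get_loc(usable[j])] = True
    return ImputedPatientTable(out, mask, candidates=candidates,
                               trace=trace, warnings=warnings)
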