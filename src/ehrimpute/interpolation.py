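"""Per-patient, time-based linear filling of continuous variables.

Vital signs such as weight, blood pressure or CD4 count drift slowly and
roughly linearly over the time spans between clinic visits, and their
variation is dominated by the individual rather than the cohort.  For
each (patient, variable) pair with at least two observations at distinct
times we fit an ordinary least-squares line ``value = a + b * t`` (t in
days since the patient's first visit) on the observed points and replace
every missing point — interior gaps *and* edge gaps, by extrapolation
along the same line — with the fitted value.  A patient with a single
observation (or all observations at one time) gets a constant fill; a
patient with no observations is left untouched for the downstream
chained-equations stage.

The unit of work is one patient and is side-effect-free, so the pass is
embarrassingly parallel and its result does not depend on how patients
are partitioned across workers.
"""

from __future__ import annotations

import numpy as np
from joblib import Parallel, delayed

from .data_model import VisitTable
from .report import StageReport, stage_report

__all__ = ["fit_and_fill", "interpolate_table"]


def fit_and_fill(times: np.ndarray, values: np.ndarray,
                 clamp: tuple | None = None) -> np.ndarray:
    """Fill missing entries of one patient series by an OLS line in time.

    ``times`` are days since the patient's first visit (nondecreasing);
    ``values`` may contain NaN.  Duplicate-time observations enter the
    fit through their mean.  Returns a new array; observed entries are
    returned bit-identical.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    obs = ~np.isnan(values)
    miss = ~obs
    if not miss.any() or not obs.any():
        return values.copy()
    t_obs, v_obs = times[obs], values[obs]
    uniq_t = np.unique(t_obs)
    out = values.copy()
    if uniq_t.size == 1:
        out[miss] = v_obs.mean()
    else:
        # collapse duplicate times to their mean, then closed-form OLS
        sums = np.zeros(uniq_t.size)
        np.add.at(sums, np.searchsorted(uniq_t, t_obs), v_obs)
        counts = np.zeros(uniq_t.size)
        np.add.at(counts, np.searchsorted(uniq_t, t_obs), 1.0)
        tm, vm = uniq_t, sums / counts
        tbar, vbar = tm.mean(), vm.mean()
        b = np.dot(tm - tbar, vm - vbar) / np.dot(tm - tbar, tm - tbar)
        a = vbar - b * tbar
        out[miss] = a + b * times[miss]
    if clamp is not None:
        lo, hi = clamp
        out[miss] = np.clip(out[miss], lo, hi)
    return out


def _fill_patient(times, block):
    """Fill every column of one patient's (n_visits, n_vars) value block."""
    return np.column_stack([fit_and_fill(times, block[:, j])
                            for j in range(block.shape[1])])


def interpolate_table(table: VisitTable, specs,
                      clamps: dict | None = None,
                      n_workers: int = 1) -> tuple:
    """Apply :func:`fit_and_fill` per (patient, eligible variable).

    Eligible variables are the continuous ones whose
    ``stage_eligibility`` includes ``interpolation``.  After the pass a
    variable is missing only for patients who never observed it.
    Returns ``(filled_table, StageReport)``.
    """
    eligible = [s.name for s in specs if s.eligible("interpolation")]
    out = table.copy()
    if not eligible:
        return out, stage_report("interpolation", table, out)

    df = out.df
    day = (df[table.date_col] - df.groupby(table.id_col)[table.date_col]
           .transform("min")).dt.days.to_numpy(dtype=float)
    vals = df[eligible].to_numpy(dtype=float)
    codes, _ = df[table.id_col].factorize()
    order = np.argsort(codes, kind="stable")
    bounds = np.flatnonzero(np.diff(codes[order])) + 1
    groups = np.split(order, bounds)

    if clamps:
        filled = vals.copy()
        for idx in groups:
            for j, name in enumerate(eligible):
                filled[idx, j] = fit_and_fill(day[idx], vals[idx, j],
                                              clamp=clamps.get(name))
    elif n_workers > 1:
        blocks = Parallel(n_jobs=n_workers)(
            delayed(_fill_patient)(day[idx], vals[idx]) for idx in groups)
        filled = vals.copy()
        for idx, block in zip(groups, blocks):
            filled[idx] = block
    else:
        filled = vals.copy()
        for idx in groups:
            filled[idx] = _fill_patient(day[idx], vals[idx])

    for j, name in enumerate(eligible):
        df[name] = filled[:, j]
    return out, stage_report("interpolation", table, out)
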