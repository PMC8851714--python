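"""Synthetic visit-level EHR generator.

Emulates the statistical structure the imputation framework assumes,
so every stage and the validation harness can run without access to any
real clinical data: overdispersed per-patient visit counts (truncated
negative binomial, mean 32 / sd 23 / max 162 by default), exponential
inter-visit gaps, continuous vitals following patient-specific
linear-in-time trajectories plus Gaussian noise, an antiretroviral
dependency chain whose blank cells are informatively missing (a blank
implies "no"), a rare binary insurance-enrollment target driven by a
logistic model on education, illness stage and age (≈7% prevalence by
default), and per-variable missingness tuned so ≈93% of variables
contain missing values and ≈42% are missing more than half of values.

The generator returns both the masked table and a :class:`GroundTruth`
(the complete table plus the mask), enabling exact recovery scoring of
every downstream stage.  No clinical realism beyond this structure is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .data_model import ConfigError, PatientTable, VisitTable

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "mask_additional",
           "correlated_pair", "ARV_CHAIN"]

#: gating variable, gate-dependent change flag, and its dependent stop reasons
ARV_CHAIN = {
    "on_arv": None,
    "arv_regimen_change": ("on_arv",),
    "arv_stop_completed_pmtct": ("on_arv", "arv_regimen_change"),
    "arv_stop_regimen_failure": ("on_arv", "arv_regimen_change"),
    "arv_stop_toxicity": ("on_arv", "arv_regimen_change"),
    "arv_stop_weight_change": ("on_arv", "arv_regimen_change"),
    "arv_stop_other": ("on_arv", "arv_regimen_change"),
    "arv_stop_new_tb": ("on_arv", "arv_regimen_change"),
    "arv_stop_nonadherence": ("on_arv", "arv_regimen_change"),
    "arv_stop_out_of_stock": ("on_arv", "arv_regimen_change"),
}

#: per-variable missing rates for the named vitals / target / dates
NAMED_MISS_RATES = {
    "body_weight": 0.101,
    "systolic_bp": 0.109,
    "diastolic_bp": 0.110,
    "cd4_count": 0.849,
    "cd4_count_date": 0.849,
    "delivery_date": 0.60,
    "nhif_enrolled": 0.797,   # target observed for ~20% of visits
    "on_arv": 0.0,            # gating variable kept complete
}

# (population mean, between-patient sd, slope-per-year sd, visit noise sd)
_NAMED_CONTINUOUS = {
    "body_weight": (62.0, 10.0, 1.5, 1.5),
    "cd4_count": (450.0, 150.0, 60.0, 40.0),
    "systolic_bp": (118.0, 12.0, 2.0, 6.0),
    "diastolic_bp": (76.0, 8.0, 1.5, 5.0),
    "bmi": (23.0, 3.0, 0.5, 0.6),
    "sao2": (97.0, 1.5, 0.3, 0.7),
    "education_years": (7.8, 3.5, 0.0, 0.0),
    "age": (28.0, 6.0, 1.0, 0.0),          # slope is exactly 1 year/year
    "age_first_pregnancy": (19.0, 3.0, 0.0, 0.0),
    "n_children_u18": (1.5, 1.0, 0.0, 0.0),
}


@dataclass
class GeneratorConfig:
    n_patients: int = 500
    visit_mean: float = 32.0
    visit_sd: float = 23.0
    visit_max: int = 162
    gap_mean_days: float = 45.0
    start_date: str = "2001-12-19"
    n_binary: int = 30          # incl. the 10-variable ARV chain and the target
    n_categorical: int = 27     # incl. WHO illness stage
    n_continuous: int = 25      # incl. the named vitals above
    n_date: int = 2
    frac_vars_with_missing: float = 0.93
    frac_missing_over_half: float = 0.42
    enrollment_prevalence: float = 0.07
    ensure_observed: bool = True
    mar: dict = field(default_factory=dict)  # var -> (driver, slope)
    seed: int = 0

    def __post_init__(self):
        if self.visit_max < self.visit_mean:
            raise ConfigError("visit_max must be >= visit_mean")
        for name, val in (("frac_vars_with_missing", self.frac_vars_with_missing),
                          ("frac_missing_over_half", self.frac_missing_over_half),
                          ("enrollment_prevalence", self.enrollment_prevalence)):
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.n_binary < 11 or self.n_continuous < len(_NAMED_CONTINUOUS):
            raise ConfigError("roster too small for the named variables")

    @property
    def n_variables(self) -> int:
        return self.n_binary + self.n_categorical + self.n_continuous + self.n_date


@dataclass
class GroundTruth:
    complete: VisitTable
    mask: pd.DataFrame          # True where the cell was masked
    params: dict


def _visit_counts(cfg: GeneratorConfig, rng) -> np.ndarray:
    """Truncated negative binomial matched to (mean, sd), capped at max, min 1."""
    mu, var = cfg.visit_mean, cfg.visit_sd ** 2
    if var <= mu:  # under-dispersed: fall back to shifted Poisson
        counts = rng.poisson(mu - 1, size=cfg.n_patients) + 1
        return np.minimum(counts, cfg.visit_max)
    size = mu * mu / (var - mu)
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p, size=cfg.n_patients)
    bad = (counts < 1) | (counts > cfg.visit_max)
    while bad.any():
        counts[bad] = rng.negative_binomial(size, p, size=int(bad.sum()))
        bad = (counts < 1) | (counts > cfg.visit_max)
    return counts


def _roster(cfg: GeneratorConfig) -> dict:
    """Variable name -> kind for the full roster."""
    kinds = {}
    for name in ARV_CHAIN:
        kinds[name] = "binary"
    kinds["nhif_enrolled"] = "binary"
    for i in range(cfg.n_binary - len(ARV_CHAIN) - 1):
        kinds[f"bin_{i:02d}"] = "binary"
    kinds["who_stage"] = "categorical"
    for i in range(cfg.n_categorical - 1):
        kinds[f"cat_{i:02d}"] = "categorical"
    for name in _NAMED_CONTINUOUS:
        kinds[name] = "continuous"
    for i in range(cfg.n_continuous - len(_NAMED_CONTINUOUS)):
        kinds[f"cont_{i:02d}"] = "continuous"
    if cfg.n_date >= 1:
        kinds["delivery_date"] = "date"
    if cfg.n_date >= 2:
        kinds["cd4_count_date"] = "date"
    for i in range(cfg.n_date - 2):
        kinds[f"date_{i:02d}"] = "date"
    return kinds


def _missing_rates(cfg: GeneratorConfig, kinds: dict, rng) -> dict:
    """Assign per-variable MCAR rates hitting the roster-level fractions."""
    names = list(kinds)
    rates = dict(NAMED_MISS_RATES)
    rates = {k: v for k, v in rates.items() if k in kinds}
    n_total = len(names)
    n_complete = round(n_total * (1.0 - cfg.frac_vars_with_missing))
    n_high = round(n_total * cfg.frac_missing_over_half)
    # complete variables beyond the gating one: generic fillers only, so the
    # ARV chain keeps missing cells for the dependency stage to work on
    generic = [n for n in names if n not in rates and n not in ARV_CHAIN]
    for name in generic[:max(0, n_complete - sum(1 for r in rates.values() if r == 0.0))]:
        rates[name] = 0.0
    pool = [n for n in names if n not in rates]
    need_high = n_high - sum(1 for r in rates.values() if r > 0.5)
    high_picks = list(rng.choice(len(pool), size=max(0, need_high), replace=False))
    for i, name in enumerate(pool):
        if i in high_picks:
            rates[name] = float(rng.uniform(0.55, 0.88))
        else:
            rates[name] = float(rng.uniform(0.05, 0.45))
    return {n: rates[n] for n in names}


def generate(cfg: GeneratorConfig) -> tuple:
    """Generate ``(masked VisitTable, GroundTruth)``; deterministic under seed."""
    rng = np.random.default_rng(cfg.seed)
    kinds = _roster(cfg)

    counts = _visit_counts(cfg, rng)
    n_pat, N = cfg.n_patients, int(counts.sum())
    pid = np.repeat([f"P{i:05d}" for i in range(n_pat)], counts)
    pidx = np.repeat(np.arange(n_pat), counts)

    start = pd.Timestamp(cfg.start_date)
    first = rng.integers(0, 365 * 8, size=n_pat)
    gaps = np.maximum(1, rng.exponential(cfg.gap_mean_days, size=N)).astype(int)
    day = np.empty(N, dtype=int)
    pos = 0
    for i, c in enumerate(counts):
        g = gaps[pos:pos + c]
        g[0] = 0
        day[pos:pos + c] = first[i] + np.cumsum(g)
        pos += c
    dates = start + pd.to_timedelta(day, unit="D")
    t_years = np.empty(N)
    pos = 0
    for i, c in enumerate(counts):
        t_years[pos:pos + c] = (day[pos:pos + c] - day[pos]) / 365.25
        pos += c

    df = pd.DataFrame({"patient_id": pid, "visit_date": dates})
    cols = {}

    # --- continuous: patient-specific affine trajectories + noise
    for name, kind in kinds.items():
        if kind != "continuous":
            continue
        if name in _NAMED_CONTINUOUS:
            mu, bsd, ssd, nsd = _NAMED_CONTINUOUS[name]
        else:
            mu = float(rng.uniform(10, 100))
            bsd, ssd, nsd = 0.2 * mu, 0.02 * mu, 0.03 * mu
        icept = mu + rng.normal(0, bsd, size=n_pat)
        slope = (np.ones(n_pat) if name == "age"
                 else rng.normal(0, ssd, size=n_pat))
        vals = icept[pidx] + slope[pidx] * t_years
        if nsd > 0:
            vals = vals + rng.normal(0, nsd, size=N)
        if name in ("education_years", "n_children_u18", "age_first_pregnancy"):
            vals = np.round(np.clip(vals, 0, None))
        if name == "cd4_count":
            vals = np.clip(vals, 1.0, None)
        cols[name] = vals

    # --- categorical: patient-level propensity with per-visit switching
    for name, kind in kinds.items():
        if kind != "categorical":
            continue
        if name == "who_stage":
            levels = np.array(["stage_1", "stage_2", "stage_3", "stage_4"])
            # illness stage loosely tied to CD4: lower CD4 -> later stage
            z = -(cols["cd4_count"] - 450.0) / 150.0 + rng.normal(0, 0.8, size=N)
            qs = np.quantile(z, [0.4, 0.7, 0.9])
            cols[name] = levels[np.searchsorted(qs, z)]
        else:
            k = int(rng.integers(3, 7))
            levels = np.array([f"{name}_l{j}" for j in range(k)])
            base = rng.integers(0, k, size=n_pat)
            switch = rng.random(N) < 0.1
            pick = np.where(switch, rng.integers(0, k, size=N), base[pidx])
            cols[name] = levels[pick]

    # --- ARV chain: blanks in the chain are informative ("no")
    p_arv = rng.beta(4, 2, size=n_pat)
    on_arv = rng.random(N) < p_arv[pidx]
    change = on_arv & (rng.random(N) < 0.02)
    cols["on_arv"] = np.where(on_arv, "yes", "no")
    cols["arv_regimen_change"] = np.where(change, "yes", "no")
    for name, deps in ARV_CHAIN.items():
        if deps is None or name == "arv_regimen_change":
            continue
        yes = change & (rng.random(N) < 0.25)
        cols[name] = np.where(yes, "yes", "no")

    # --- generic binaries
    for name, kind in kinds.items():
        if kind == "binary" and name not in cols and name != "nhif_enrolled":
            p = rng.beta(2, 5, size=n_pat)
            cols[name] = np.where(rng.random(N) < p[pidx], "yes", "no")

    # --- enrollment target: a patient-level administrative state, logistic in
    # education, illness stage and age; time-variant through a switch-on visit
    # for half of the enrolled patients.  Intercept calibrated so the
    # visit-level prevalence matches the configured value.
    stage_num = np.searchsorted(
        np.array(["stage_1", "stage_2", "stage_3", "stage_4"]), cols["who_stage"])
    pat_stage = np.bincount(pidx, weights=stage_num) / counts
    pat_edu = np.bincount(pidx, weights=cols["education_years"]) / counts
    pat_age = np.bincount(pidx, weights=cols["age"]) / counts
    lp = (1.0 * (pat_edu - pat_edu.mean()) / max(pat_edu.std(), 1e-9)
          + 0.8 * (pat_stage - pat_stage.mean())
          + 0.5 * (pat_age - pat_age.mean()) / max(pat_age.std(), 1e-9))
    switch_frac = np.where(rng.random(n_pat) < 0.5, 0.0,
                           rng.random(n_pat))  # fraction of visits pre-enrollment
    w = counts / counts.sum()
    b0 = brentq(lambda b: float(np.sum(w * expit(b + lp) * (1 - switch_frac)))
                - cfg.enrollment_prevalence, -20, 20)
    enrolled = rng.random(n_pat) < expit(b0 + lp)
    visit_no = np.concatenate([np.arange(c) for c in counts])
    on_after = visit_no >= np.ceil(switch_frac * counts)[pidx]
    cols["nhif_enrolled"] = np.where(enrolled[pidx] & on_after, "yes", "no")

    # --- dates
    if "delivery_date" in kinds:
        deliv = start + pd.to_timedelta(
            first + rng.integers(-200, 100, size=n_pat), unit="D")
        cols["delivery_date"] = pd.DatetimeIndex(np.asarray(deliv)[pidx])
    if "cd4_count_date" in kinds:
        cols["cd4_count_date"] = dates - pd.to_timedelta(
            rng.integers(0, 30, size=N), unit="D")

    for name in kinds:
        df[name] = cols[name]

    # --- masking
    rates = _missing_rates(cfg, kinds, rng)
    mask = pd.DataFrame(False, index=df.index, columns=list(kinds))
    for name, kind in kinds.items():
        rate = rates[name]
        if rate <= 0:
            continue
        if name in cfg.mar:
            driver, slope = cfg.mar[name]
            dv = pd.to_numeric(pd.Series(cols[driver]), errors="coerce").to_numpy()
            z = slope * (dv - np.nanmean(dv)) / max(np.nanstd(dv), 1e-9)
            a = brentq(lambda b: expit(b + z).mean() - rate, -20, 20)
            m = rng.random(N) < expit(a + z)
        else:
            m = rng.random(N) < rate
        if name in ARV_CHAIN and ARV_CHAIN[name] is not None:
            # informative missingness: only true-"no" cells can be blank
            m &= np.asarray(cols[name]) == "no"
        mask[name] = m
    if cfg.ensure_observed:
        for name in kinds:
            if mask[name].all():
                mask.iloc[int(rng.integers(N)), mask.columns.get_loc(name)] = False

    complete_df = df.copy()
    masked_df = df.copy()
    for name, kind in kinds.items():
        col = masked_df[name]
        if kind in ("continuous",):
            masked_df[name] = col.where(~mask[name], np.nan)
        elif kind == "date":
            masked_df[name] = col.where(~mask[name], pd.NaT)
        else:
            masked_df[name] = col.astype(object).where(~mask[name], np.nan)
        if kind in ("binary", "categorical"):
            complete_df[name] = complete_df[name].astype(object)

    complete = VisitTable(df=complete_df, kinds=dict(kinds)).sort()
    masked = VisitTable(df=masked_df, kinds=dict(kinds)).sort()
    # apply the same stable ordering to the mask so rows stay aligned
    order = (df.assign(_i=np.arange(N))
             .sort_values(["patient_id", "visit_date"], kind="stable")["_i"].to_numpy())
    mask = mask.iloc[order].reset_index(drop=True)

    params = {
        "n_patients": n_pat, "n_visits": N, "n_variables": len(kinds),
        "visit_mean": float(counts.mean()), "visit_sd": float(counts.std()),
        "visit_max": int(counts.max()),
        "enrollment_prevalence": float(np.mean(np.asarray(
            complete_df["nhif_enrolled"]) == "yes")),
        "missing_rates": rates, "seed": cfg.seed,
        "enrollment_intercept": float(b0),
    }
    return masked, GroundTruth(complete=complete, mask=mask, params=params)


def mask_additional(table: VisitTable, rate: float, mechanism: str = "mcar",
                    seed: int = 0, variables=None, driver: str | None = None,
                    slope: float = 1.0) -> tuple:
    """Mask currently observed cells for held-out recovery scoring.

    MCAR masks each observed cell independently with ``rate``; MAR makes
    the masking probability logistic in the (observed) ``driver``
    variable, calibrated so the mean rate equals ``rate``.  Errors if a
    variable would be left with zero observed values.
    """
    if not 0.0 < rate < 1.0:
        raise ConfigError("rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = table.copy()
    variables = list(variables) if variables is not None else out.variables
    mask = pd.DataFrame(False, index=out.df.index, columns=variables)
    for name in variables:
        col = out.df[name]
        obs = col.notna().to_numpy()
        if mechanism == "mar":
            if driver is None:
                raise ConfigError("MAR masking needs a driver variable")
            dv = pd.to_numeric(out.df[driver], errors="coerce").to_numpy(dtype=float)
            z = slope * (dv - np.nanmean(dv)) / max(np.nanstd(dv), 1e-9)
            z = np.where(np.isnan(z), 0.0, z)
            a = brentq(lambda b: expit(b + z[obs]).mean() - rate, -30, 30)
            m = obs & (rng.random(len(col)) < expit(a + z))
        elif mechanism == "mcar":
            m = obs & (rng.random(len(col)) < rate)
        else:
            raise ConfigError(f"unknown mechanism {mechanism!r}")
        if (obs & ~m).sum() == 0:
            raise ConfigError(f"masking would leave {name!r} with no observed values")
        mask[name] = m
        kind = out.kinds[name]
        if kind == "continuous":
            out.df[name] = col.where(~m, np.nan)
        elif kind == "date":
            out.df[name] = col.where(~m, pd.NaT)
        else:
            out.df[name] = col.astype(object).where(~m, np.nan)
    return out, mask


def correlated_pair(n: int, r: float = 0.95, missing_rate: float = 0.2,
                    mechanism: str = "mar", seed: int = 0) -> tuple:
    """Patient-level table with two correlated continuous variables.

    ``y = r*x + sqrt(1-r^2)*noise`` (unit variances); ``missing_rate``
    of y cells are masked, MAR-driven by x (logistic link) by default.
    Returns ``(PatientTable, truth_y, mask)`` for imputation scoring.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = r * x + np.sqrt(1.0 - r * r) * rng.normal(size=n)
    if mechanism == "mar":
        z = 1.5 * x
        a = brentq(lambda b: expit(b + z).mean() - missing_rate, -30, 30)
        m = rng.random(n) < expit(a + z)
    else:
        m = rng.random(n) < missing_rate
    if m.all() or not m.any():
        raise ConfigError("degenerate mask; adjust rate or seed")
    df = pd.DataFrame({
        "patient_id": [f"P{i:05d}" for i in range(n)],
        "x": x,
        "y": np.where(m, np.nan, y),
    })
    table = PatientTable(df=df, kinds={"x": "continuous", "y": "continuous"},
                         provenance=pd.Series(np.arange(n), index=df["patient_id"]))
    return table, y, m
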