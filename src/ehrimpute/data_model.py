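"""Core table and metadata types shared by every imputation stage.

The package works on a *visit-level* long table: one row per clinic
encounter, identified by a patient id and a visit date, with a mixed set
of binary / categorical / continuous / date variables in the remaining
columns.  Missingness is always an explicit state (``NaN`` / ``NaT`` in
the typed frame), never a sentinel value: an empty string, a ``0`` or a
``"no"`` read from a file are observed values.

Two invariants every stage relies on:

* rows are stably ordered by visit date within each patient (ties keep
  file order — same-day visits are legitimate EHR events and are kept);
* originally observed cells are never modified by any stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "DataError",
    "VariableSpec",
    "VisitTable",
    "PatientTable",
    "read_visit_table",
    "write_visit_table",
    "infer_specs",
    "load_schema",
    "missing_mask",
    "missing_counts",
]

#: tokens accepted as explicit missing markers on read (empty written on write)
MISSING_TOKENS = frozenset({"", "NA"})

KINDS = ("binary", "categorical", "continuous", "date")
STAGES = ("dependency_fill", "interpolation", "mice", "date_locf")

_BINARY_LEXICON = {
    "yes": "yes", "1": "yes", "true": "yes",
    "no": "no", "0": "no", "false": "no",
}


class ConfigError(ValueError):
    """Invalid configuration (rules, schema, pipeline settings)."""


class DataError(ValueError):
    """Structurally invalid input data (missing columns, bad dates)."""


@dataclass(frozen=True)
class VariableSpec:
    """Per-variable metadata: semantic type and stage eligibility.

    A continuous variable is eligible for per-patient interpolation iff
    it has at least ``interp_min_unique`` (default 10) distinct observed
    values.  Date variables are handled exclusively by last-observation
    carry-forward and are never chained-equations targets.
    """

    name: str
    kind: str
    unique_value_count: int = 0
    stage_eligibility: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        bad = set(self.stage_eligibility) - set(STAGES)
        if bad:
            raise ConfigError(f"unknown stages {sorted(bad)} for {self.name!r}")

    def eligible(self, stage: str) -> bool:
        return stage in self.stage_eligibility


@dataclass
class VisitTable:
    """Long-format visit-level table with explicit missingness.

    ``df`` holds typed columns: the id column (object), the date column
    (datetime64), continuous variables as float64 (NaN = missing),
    binary/categorical variables as object with canonical string levels
    (NaN = missing; binary levels are ``"yes"``/``"no"`` internally) and
    date variables as datetime64 (NaT = missing).  ``lexicon`` remembers
    the lexical form each binary column used in its source file so
    writing restores it.
    """

    df: pd.DataFrame
    kinds: dict
    id_col: str = "patient_id"
    date_col: str = "visit_date"
    lexicon: dict = field(default_factory=dict)
    date_format: str = "%Y-%m-%d"

    @property
    def variables(self) -> list:
        return [c for c in self.df.columns if c not in (self.id_col, self.date_col)]

    @property
    def n_patients(self) -> int:
        return self.df[self.id_col].nunique()

    def copy(self) -> "VisitTable":
        return replace(self, df=self.df.copy(), kinds=dict(self.kinds),
                       lexicon={k: dict(v) for k, v in self.lexicon.items()})

    def sort(self) -> "VisitTable":
        """Stable sort by (patient, visit date); same-day ties keep input order."""
        out = self.copy()
        out.df = (out.df.sort_values([self.id_col, self.date_col], kind="stable")
                  .reset_index(drop=True))
        return out


@dataclass
class PatientTable:
    """One row per patient, same variable columns as the source visit table.

    ``provenance`` maps each patient id to the row index of the visit
    chosen to represent them, so every cell is traceable to one source row.
    """

    df: pd.DataFrame
    kinds: dict
    provenance: pd.Series
    id_col: str = "patient_id"
    lexicon: dict = field(default_factory=dict)

    @property
    def variables(self) -> list:
        return [c for c in self.df.columns if c != self.id_col]

    def copy(self) -> "PatientTable":
        return replace(self, df=self.df.copy(), kinds=dict(self.kinds),
                       provenance=self.provenance.copy())


# ---------------------------------------------------------------------------
# type inference & conversion

def _observed_strings(col: pd.Series) -> pd.Series:
    return col[~col.isin(MISSING_TOKENS)]


def _infer_kind(col: pd.Series, date_format: str) -> str:
    obs = _observed_strings(col)
    if obs.empty:
        return "categorical"
    parsed = pd.to_datetime(obs, format=date_format, errors="coerce")
    if parsed.notna().all():
        return "date"
    if obs.str.lower().isin(_BINARY_LEXICON).all():
        return "binary"
    if pd.to_numeric(obs, errors="coerce").notna().all():
        return "continuous"
    return "categorical"


def _convert(col: pd.Series, kind: str, date_format: str):
    """Convert a raw string column to its typed form; returns (series, lexicon)."""
    miss = col.isin(MISSING_TOKENS)
    if kind == "continuous":
        out = pd.to_numeric(col.where(~miss), errors="coerce").astype(float)
        return out, None
    if kind == "date":
        out = pd.to_datetime(col.where(~miss), format=date_format, errors="coerce")
        bad = (~miss) & out.isna()
        if bad.any():
            raise DataError(
                f"unparseable date {col[bad].iloc[0]!r} in column {col.name!r} "
                f"(row {int(bad.idxmax()) + 2} of file)")
        return out, None
    if kind == "binary":
        lower = col.str.lower()
        canon = lower.map(_BINARY_LEXICON)
        bad = (~miss) & canon.isna()
        if bad.any():
            raise DataError(
                f"non-binary value {col[bad].iloc[0]!r} in binary column {col.name!r}")
        # remember the majority lexical form per canonical level for writing
        lex = {}
        for level in ("yes", "no"):
            forms = col[(canon == level)]
            if not forms.empty:
                lex[level] = forms.mode(dropna=True).iloc[0]
        out = canon.where(~miss)
        out = out.astype(object).where(out.notna(), np.nan)
        return out, lex
    out = col.astype(object).where(~miss, np.nan)
    return out, None


def read_visit_table(path, schema=None, id_col: str = "patient_id",
                     date_col: str = "visit_date",
                     date_format: str = "%Y-%m-%d") -> VisitTable:
    """Read a visit-level CSV into a typed :class:`VisitTable`.

    Empty fields and the literal ``NA`` are read as missing.  When
    ``schema`` (a mapping ``name -> kind`` or ``name -> {"kind": ...}``)
    is absent, kinds are inferred per column: fully date-parseable →
    date; values within {yes,no,1,0,true,false} → binary; numeric →
    continuous; anything else categorical.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (id_col, date_col):
        if col not in raw.columns:
            raise DataError(f"required column {col!r} not found in {path}")
    miss_id = raw[id_col].isin(MISSING_TOKENS)
    if miss_id.any():
        raise DataError(f"missing patient id at file row {int(miss_id.idxmax()) + 2}")
    miss_dt = raw[date_col].isin(MISSING_TOKENS)
    if miss_dt.any():
        raise DataError(f"missing visit date at file row {int(miss_dt.idxmax()) + 2}")
    dates = pd.to_datetime(raw[date_col], format=date_format, errors="coerce")
    if dates.isna().any():
        bad = int(dates.isna().idxmax())
        raise DataError(
            f"unparseable visit date {raw[date_col].iloc[bad]!r} at file row {bad + 2}")

    if schema is not None:
        schema = {k: (v["kind"] if isinstance(v, dict) else v) for k, v in schema.items()}

    df = pd.DataFrame({id_col: raw[id_col].astype(object), date_col: dates})
    kinds, lexicon = {}, {}
    for name in raw.columns:
        if name in (id_col, date_col):
            continue
        kind = (schema or {}).get(name) or _infer_kind(raw[name], date_format)
        if kind not in KINDS:
            raise ConfigError(f"schema assigns unknown kind {kind!r} to {name!r}")
        df[name], lex = _convert(raw[name], kind, date_format)
        kinds[name] = kind
        if lex:
            lexicon[name] = lex
    table = VisitTable(df=df, kinds=kinds, id_col=id_col, date_col=date_col,
                       lexicon=lexicon, date_format=date_format)
    return table.sort()


def write_visit_table(table: VisitTable, path) -> None:
    """Write a :class:`VisitTable` back to CSV (missing cells → empty field).

    Binary columns are written in the lexical form recorded at read time;
    floats use Python ``repr`` formatting so read→write→read round-trips
    values bit-exactly.
    """
    out = table.df.copy()
    for name, kind in table.kinds.items():
        if kind == "binary":
            lex = table.lexicon.get(name, {})
            col = out[name]
            out[name] = col.map(lambda v: lex.get(v, v) if isinstance(v, str) else v)
        elif kind == "date":
            out[name] = out[name].dt.strftime(table.date_format)
    out[table.date_col] = out[table.date_col].dt.strftime(table.date_format)
    out.to_csv(path, index=False, na_rep="")


def infer_specs(table: VisitTable, interp_min_unique: int = 10,
                overrides: dict | None = None) -> list:
    """Build one :class:`VariableSpec` per variable column.

    Eligibility by kind: binary → dependency_fill + mice; categorical →
    mice; continuous → mice, plus interpolation when the observed unique
    count reaches ``interp_min_unique``; date → date_locf only.
    ``overrides`` may pin ``{"stages": [...]}`` per variable.
    """
    specs = []
    for name in table.variables:
        kind = table.kinds[name]
        col = table.df[name]
        nuniq = int(col.nunique(dropna=True))
        if kind == "binary":
            stages = {"dependency_fill", "mice"}
        elif kind == "categorical":
            stages = {"mice"}
        elif kind == "continuous":
            stages = {"mice"}
            if nuniq >= interp_min_unique:
                stages.add("interpolation")
        else:
            stages = {"date_locf"}
        ov = (overrides or {}).get(name, {})
        if "stages" in ov:
            stages = set(ov["stages"])
        specs.append(VariableSpec(name=name, kind=kind, unique_value_count=nuniq,
                                  stage_eligibility=frozenset(stages)))
    return specs


def load_schema(path) -> dict:
    """Load a YAML/JSON variable schema: ``name -> {kind, stages?}``."""
    with open(path) as fh:
        text = fh.read()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError("variable schema must be a mapping of name -> settings")
    return data


def missing_mask(table) -> pd.DataFrame:
    """Boolean frame over variable columns: True where the cell is missing."""
    return table.df[table.variables].isna()


def missing_counts(table) -> pd.Series:
    """Per-variable count of missing cells."""
    return missing_mask(table).sum()
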