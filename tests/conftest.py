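import numpy as np
import pandas as pd
import pytest

from ehrimpute.data_model import VisitTable


def make_table(columns: dict, kinds: dict, id_col="patient_id",
               date_col="visit_date") -> VisitTable:
    """Build a typed VisitTable from plain dict columns (None = missing)."""
    df = pd.DataFrame(columns)
    df[date_col] = pd.to_datetime(df[date_col])
    for name, kind in kinds.items():
        col = df[name]
        if kind == "continuous":
            df[name] = pd.to_numeric(col, errors="coerce").astype(float)
        elif kind == "date":
            df[name] = pd.to_datetime(col)
        else:
            df[name] = col.astype(object).where(col.notna(), np.nan)
    return VisitTable(df=df, kinds=dict(kinds), id_col=id_col,
                      date_col=date_col).sort()


def tables_equal(a: VisitTable, b: VisitTable) -> bool:
    try:
        pd.testing.assert_frame_equal(a.df, b.df, check_dtype=False)
        return True
    except AssertionError:
        return False


@pytest.fixture(scope="session")
def arv_rules():
    from ehrimpute import builtin_rules_path
    from ehrimpute.dependency_rules import load_rules
    return load_rules(builtin_rules_path())


@pytest.fixture(scope="session")
def small_synthetic():
    """Masked table + ground truth, 120 patients (shared to keep the suite fast)."""
    from ehrimpute.synthetic_data import GeneratorConfig, generate
    return generate(GeneratorConfig(n_patients=120, seed=11))


@pytest.fixture(scope="session")
def pipeline_run(small_synthetic, arv_rules):
    """One full pipeline run on the shared synthetic table."""
    from ehrimpute import PipelineConfig, infer_specs, run_pipeline
    masked, truth = small_synthetic
    specs = infer_specs(masked)
    filled, reports = run_pipeline(masked, arv_rules, specs, PipelineConfig(seed=3))
    return masked, truth, specs, filled, reports
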