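import numpy as np
import pandas as pd
import pytest

from ehrimpute.data_model import DataError, PatientTable, VariableSpec
from ehrimpute.mice_engine import MiceConfig, mice_impute
from ehrimpute.synthetic_data import correlated_pair


def make_patient_table(columns: dict, kinds: dict) -> PatientTable:
    df = pd.DataFrame(columns)
    for name, kind in kinds.items():
        if kind == "continuous":
            df[name] = pd.to_numeric(df[name], errors="coerce").astype(float)
        else:
            df[name] = df[name].astype(object).where(df[name].notna(), np.nan)
    df.insert(0, "patient_id", [f"p{i}" for i in range(len(df))])
    prov = pd.Series(np.arange(len(df)), index=df["patient_id"])
    return PatientTable(df=df, kinds=dict(kinds), provenance=prov)


def specs_for(kinds):
    return [VariableSpec(name=k, kind=v, unique_value_count=10,
                         stage_eligibility=frozenset({"mice"}))
            for k, v in kinds.items()]


def test_complete_table_returned_unchanged_with_empty_mask():
    kinds = {"a": "continuous", "b": "binary"}
    t = make_patient_table({"a": [1.0, 2.0, 3.0], "b": ["yes", "no", "yes"]}, kinds)
    out = mice_impute(t, specs_for(kinds), MiceConfig(seed=0))
    pd.testing.assert_frame_equal(out.table.df, t.df)
    assert not out.imputed_mask.any().any()


def test_observed_cells_conserved_and_donor_range_invariant():
    rng = np.random.default_rng(0)
    kinds = {"x": "continuous", "y": "continuous", "c": "categorical"}
    n = 120
    x = rng.normal(size=n)
    y = x + rng.normal(scale=0.2, size=n)
    c = rng.choice(["u", "v", "w"], size=n).astype(object)
    y[rng.random(n) < 0.3] = np.nan
    c[rng.random(n) < 0.3] = None
    t = make_patient_table({"x": x, "y": y, "c": list(c)}, kinds)
    out = mice_impute(t, specs_for(kinds), MiceConfig(seed=1))
    for col in ("x", "y", "c"):
        obs = t.df[col].notna()
        assert (out.table.df[col][obs] == t.df[col][obs]).all()
    # donor draws can only produce observed values
    observed_y = set(t.df["y"].dropna())
    assert set(out.table.df["y"][t.df["y"].isna()]) <= observed_y
    assert set(out.table.df["c"].dropna()) <= {"u", "v", "w"}
    assert out.table.df[["x", "y", "c"]].notna().all().all()


def test_binary_imputations_are_canonical_levels():
    rng = np.random.default_rng(2)
    kinds = {"x": "continuous", "b": "binary"}
    n = 80
    b = np.where(rng.random(n) < 0.5, "yes", "no").astype(object)
    b[rng.random(n) < 0.4] = None
    t = make_patient_table({"x": rng.normal(size=n), "b": list(b)}, kinds)
    out = mice_impute(t, specs_for(kinds), MiceConfig(seed=3))
    assert set(out.table.df["b"]) <= {"yes", "no"}


def test_seed_determinism_and_sensitivity():
    table, _, _ = correlated_pair(200, seed=5)
    specs = specs_for({"x": "continuous", "y": "continuous"})
    a = mice_impute(table, specs, MiceConfig(seed=7)).table.df
    b = mice_impute(table, specs, MiceConfig(seed=7)).table.df
    c = mice_impute(table, specs, MiceConfig(seed=8)).table.df
    pd.testing.assert_frame_equal(a, b)
    assert not a["y"].equals(c["y"])


@pytest.mark.parametrize("pooling", ["per_cell_random", "per_copy_random"])
def test_pooled_values_come_from_candidate_copies(pooling):
    table, _, mask = correlated_pair(150, seed=9)
    specs = specs_for({"x": "continuous", "y": "continuous"})
    out = mice_impute(table, specs, MiceConfig(seed=4, pooling=pooling))
    rows, cands = out.candidates["y"]
    final = out.table.df["y"].to_numpy()[rows]
    assert all(final[i] in cands[i] for i in range(len(rows)))
    assert cands.shape[1] == 5  # m copies retained for diagnostics


def test_beats_mean_imputation_on_correlated_mar_data():
    wins = 0
    for seed in range(5):
        table, truth_y, m = correlated_pair(500, r=0.95, missing_rate=0.2, seed=seed)
        specs = specs_for({"x": "continuous", "y": "continuous"})
        out = mice_impute(table, specs, MiceConfig(seed=seed))
        imputed = out.table.df["y"].to_numpy()
        rmse = np.sqrt(np.mean((imputed[m] - truth_y[m]) ** 2))
        baseline = np.sqrt(np.mean((np.nanmean(table.df["y"]) - truth_y[m]) ** 2))
        wins += rmse < baseline
    assert wins >= 4


def test_one_cell_one_split_donor_enumeration():
    # x <= 0.5 separates donors {10, 12} from {30, 34}; the missing cell has
    # x = 0.9, so its imputed value must come from the right leaf.
    kinds = {"x": "continuous", "y": "continuous"}
    t = make_patient_table({"x": [0.0, 0.2, 0.8, 1.0, 0.9],
                            "y": [10.0, 12.0, 30.0, 34.0, None]}, kinds)
    out = mice_impute(t, specs_for(kinds),
                      MiceConfig(m=1, iterations=1, min_leaf_size=1, seed=0))
    assert out.table.df["y"].iloc[4] in {30.0, 34.0}


def test_all_missing_variable_left_missing_with_warning():
    kinds = {"x": "continuous", "z": "continuous"}
    t = make_patient_table({"x": [1.0, 2.0, 3.0, 4.0],
                            "z": [None] * 4}, kinds)
    out = mice_impute(t, specs_for(kinds), MiceConfig(seed=0))
    assert out.table.df["z"].isna().all()
    assert any("z" in w for w in out.warnings)


def test_single_row_table_has_no_donors():
    kinds = {"x": "continuous"}
    t = make_patient_table({"x": [1.0]}, kinds)
    with pytest.raises(DataError, match="donor"):
        mice_impute(t, specs_for(kinds), MiceConfig(seed=0))


def test_convergence_trace_is_logged_per_copy_and_variable():
    table, _, _ = correlated_pair(100, seed=1)
    cfg = MiceConfig(seed=0, m=2, iterations=3)
    out = mice_impute(table, specs_for({"x": "continuous", "y": "continuous"}), cfg)
    assert len(out.trace[(0, "y")]) == 3
    assert len(out.trace) == 2  # one trace per copy for the one missing variable
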