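import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrimpute.data_model import infer_specs
from ehrimpute.interpolation import fit_and_fill, interpolate_table

from conftest import make_table


def ols_oracle(times, values):
    """Normal-equations OLS after collapsing duplicate times to their mean."""
    obs = ~np.isnan(values)
    t, v = times[obs], values[obs]
    uniq = np.unique(t)
    vm = np.array([v[t == u].mean() for u in uniq])
    A = np.column_stack([np.ones_like(uniq), uniq])
    a, b = np.linalg.solve(A.T @ A, A.T @ vm)
    return a, b


def test_two_point_line_fills_midpoint():
    out = fit_and_fill(np.array([0.0, 2.0, 4.0]), np.array([10.0, np.nan, 20.0]))
    assert out[1] == pytest.approx(15.0, abs=1e-12)


def test_fully_observed_series_unchanged():
    v = np.array([1.0, 2.0, 3.0])
    assert np.array_equal(fit_and_fill(np.array([0.0, 1.0, 2.0]), v), v)


def test_single_observation_constant_fill_including_edges():
    out = fit_and_fill(np.array([0.0, 3.0, 7.0]), np.array([np.nan, 62.0, np.nan]))
    assert out.tolist() == [62.0, 62.0, 62.0]


def test_all_times_identical_fills_with_mean():
    out = fit_and_fill(np.array([5.0, 5.0, 5.0]),
                       np.array([10.0, 20.0, np.nan]))
    assert out[2] == pytest.approx(15.0)


def test_zero_observations_left_for_downstream():
    v = np.array([np.nan, np.nan])
    assert np.isnan(fit_and_fill(np.array([0.0, 1.0]), v)).all()


def test_exact_recovery_on_affine_ground_truth():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(4, 30))
        t = np.sort(rng.uniform(0, 300, size=n))
        truth = 5.0 + 0.5 * t
        v = truth.copy()
        mask = rng.random(n) < 0.4
        mask[rng.integers(n)] = False  # keep >= 1 observed
        if (~mask).sum() < 2:
            continue
        v[mask] = np.nan
        out = fit_and_fill(t, v)
        assert np.max(np.abs(out - truth)) < 1e-9


@pytest.mark.parametrize("seed", range(10))
def test_fitted_line_matches_normal_equations_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 40))
    t = np.sort(rng.uniform(0, 100, size=n))
    if seed % 3 == 0:
        t[1] = t[0]  # duplicate times with different values
    v = rng.normal(50, 10, size=n)
    v[rng.integers(n)] = np.nan
    if np.isnan(v).all() or np.unique(t[~np.isnan(v)]).size < 2:
        pytest.skip("degenerate draw")
    a, b = ols_oracle(t, v)
    out = fit_and_fill(t, v)
    miss = np.isnan(v)
    assert np.allclose(out[miss], a + b * t[miss], atol=1e-9)


def test_observed_values_bit_identical_after_fill():
    rng = np.random.default_rng(3)
    t = np.sort(rng.uniform(0, 50, 20))
    v = rng.normal(size=20)
    v[::3] = np.nan
    out = fit_and_fill(t, v)
    obs = ~np.isnan(v)
    assert np.array_equal(out[obs], v[obs])


def test_optional_clamp_applies_to_filled_cells_only():
    out = fit_and_fill(np.array([0.0, 10.0, 20.0]),
                       np.array([0.0, np.nan, 200.0]), clamp=(0.0, 90.0))
    assert out[1] == 90.0 and out[2] == 200.0


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 1000),
                          st.one_of(st.none(),
                                    st.floats(-1e3, 1e3, allow_nan=False))),
                min_size=1, max_size=25))
def test_fill_is_total_and_conserves_observations(points):
    """Filling never alters observed values, and leaves gaps only when the
    patient has no observations at all."""
    t = np.sort(np.array([p[0] for p in points], dtype=float))
    v = np.array([np.nan if p[1] is None else p[1] for p in points])
    out = fit_and_fill(t, v)
    obs = ~np.isnan(v)
    assert np.array_equal(out[obs], v[obs])
    if obs.any():
        assert not np.isnan(out).any()
    else:
        assert np.isnan(out).all()


# ---------------------------------------------------------------------------

def _interp_table():
    n = 12
    dates = list(pd.date_range("2020-01-01", periods=n, freq="7D"))
    w = [50 + i for i in range(n)]
    w[3] = w[8] = None
    return make_table({
        "patient_id": ["a"] * n + ["b"] * n,
        "visit_date": dates * 2,
        "weight": w + [None] * n,          # patient b never observes weight
        "flag": (["yes", None] * n)[:2 * n],
    }, {"weight": "continuous", "flag": "binary"})


def test_table_pass_fills_only_patients_with_observations():
    t = _interp_table()
    specs = infer_specs(t, interp_min_unique=5)
    out, rep = interpolate_table(t, specs)
    a_rows = out.df["patient_id"] == "a"
    assert out.df.loc[a_rows, "weight"].notna().all()
    assert out.df.loc[~a_rows, "weight"].isna().all()   # zero-observation set
    assert rep.per_variable["weight"]["missing_after"] == 12


def test_ineligible_variables_untouched():
    t = _interp_table()
    specs = infer_specs(t, interp_min_unique=5)
    out, _ = interpolate_table(t, specs)
    pd.testing.assert_series_equal(out.df["flag"], t.df["flag"])


def test_worker_count_does_not_change_results(small_synthetic):
    from ehrimpute.data_model import infer_specs
    masked, _ = small_synthetic
    specs = infer_specs(masked)
    out1, _ = interpolate_table(masked, specs, n_workers=1)
    out3, _ = interpolate_table(masked, specs, n_workers=3)
    pd.testing.assert_frame_equal(out1.df, out3.df)
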