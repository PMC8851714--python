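import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrimpute.data_model import ConfigError
from ehrimpute.dependency_rules import (DependencyRule, apply_rules, load_rules,
                                        toposort_rules)

from conftest import make_table

CHAIN = [
    DependencyRule(target="change", antecedents=(("on_arv", "yes"),)),
    DependencyRule(target="stop_tox",
                   antecedents=(("on_arv", "yes"), ("change", "no_or_filled"))),
]


def chain_table(on_arv, change, stop):
    n = len(on_arv)
    return make_table({
        "patient_id": [f"p{i}" for i in range(n)],
        "visit_date": ["2020-01-01"] * n,
        "on_arv": on_arv, "change": change, "stop_tox": stop,
    }, {"on_arv": "binary", "change": "binary", "stop_tox": "binary"})


def brute_force_fill(on_arv, change, stop):
    """Row-by-row enumeration of the two-rule chain semantics."""
    out_change, out_stop, filled = [], [], 0
    for a, c, s in zip(on_arv, change, stop):
        if c is None and a == "yes":
            c, filled = "no", filled + 1
        if s is None and a == "yes" and c == "no":
            s, filled = "no", filled + 1
        out_change.append(c)
        out_stop.append(s)
    return out_change, out_stop, filled


def test_chained_fill_through_two_levels():
    t = chain_table(["yes"], [None], [None])
    out, log = apply_rules(t, CHAIN)
    assert out.df["change"].iloc[0] == "no"
    assert out.df["stop_tox"].iloc[0] == "no"  # filled "no" satisfies rule 2
    assert log.total_filled == 2


def test_failed_antecedent_blocks_fill():
    t = chain_table(["no"], [None], [None])
    out, log = apply_rules(t, CHAIN)
    assert out.df["change"].isna().all() and out.df["stop_tox"].isna().all()
    assert log.total_filled == 0


def test_missing_antecedent_is_never_speculatively_filled():
    t = chain_table([None], [None], [None])
    out, _ = apply_rules(t, CHAIN)
    assert out.df.loc[:, ["change", "stop_tox"]].isna().all().all()


def test_six_row_toy_matches_hand_enumeration():
    on_arv = ["yes", "yes", "no", "yes", None, "no"]
    change = [None, "yes", None, "no", None, "no"]
    stop = [None, None, None, None, "yes", None]
    t = chain_table(on_arv, change, stop)
    out, log = apply_rules(t, CHAIN)
    exp_change, exp_stop, exp_filled = brute_force_fill(on_arv, change, stop)
    assert log.total_filled == exp_filled
    got_change = [v if isinstance(v, str) else None for v in out.df["change"]]
    got_stop = [v if isinstance(v, str) else None for v in out.df["stop_tox"]]
    assert got_change == exp_change
    assert got_stop == exp_stop
    # fill log yes-counts unchanged: fills only ever add "no"
    for v, rec in log.per_variable.items():
        assert rec["yes_after"] == rec["yes_before"]
        assert rec["filled"] <= rec["missing_before"]


@pytest.mark.parametrize("n_tables", [200])
def test_idempotence_and_conservation_on_fuzzed_tables(n_tables):
    rng = np.random.default_rng(42)
    states = np.array(["yes", "no", None], dtype=object)
    for _ in range(n_tables):
        n = int(rng.integers(1, 12))
        t = chain_table(*(list(rng.choice(states, size=n)) for _ in range(3)))
        once, _ = apply_rules(t, CHAIN)
        twice, log2 = apply_rules(once, CHAIN)
        pd.testing.assert_frame_equal(once.df, twice.df)
        assert log2.total_filled == 0
        # observed cells unchanged, missingness never increases
        for v in t.variables:
            obs = t.df[v].notna()
            assert (once.df[v][obs] == t.df[v][obs]).all()
            assert once.df[v].isna().sum() <= t.df[v].isna().sum()


_cell = st.sampled_from(["yes", "no", None])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.tuples(_cell, _cell, _cell), min_size=1, max_size=10))
def test_fill_matches_row_enumeration_on_arbitrary_tables(rows):
    """The vectorized engine agrees with per-row enumeration of the chain."""
    on_arv, change, stop = map(list, zip(*rows))
    out, log = apply_rules(chain_table(on_arv, change, stop), CHAIN)
    exp_change, exp_stop, exp_filled = brute_force_fill(on_arv, change, stop)
    assert log.total_filled == exp_filled
    assert [v if isinstance(v, str) else None
            for v in out.df["change"]] == exp_change
    assert [v if isinstance(v, str) else None
            for v in out.df["stop_tox"]] == exp_stop


def test_result_independent_of_declared_rule_order():
    rng = np.random.default_rng(7)
    states = np.array(["yes", "no", None], dtype=object)
    t = chain_table(*(list(rng.choice(states, size=30)) for _ in range(3)))
    out_fwd, _ = apply_rules(t, CHAIN)
    out_rev, _ = apply_rules(t, list(reversed(CHAIN)))
    pd.testing.assert_frame_equal(out_fwd.df, out_rev.df)


def test_bundled_arv_rules_load_and_order(arv_rules):
    assert len(arv_rules) == 9
    ordered = toposort_rules(arv_rules)
    assert ordered[0].target == "arv_regimen_change"
    assert all(("arv_regimen_change", "no_or_filled") in r.antecedents
               for r in ordered[1:])


def test_empty_rules_file_is_identity(tmp_path):
    path = tmp_path / "rules.yaml"
    path.write_text("")
    assert load_rules(path) == []
    t = chain_table(["yes"], [None], [None])
    out, log = apply_rules(t, [])
    pd.testing.assert_frame_equal(out.df, t.df)
    assert log.total_filled == 0


def test_self_antecedent_rejected():
    with pytest.raises(ConfigError):
        DependencyRule(target="a", antecedents=(("a", "yes"),))


def test_cyclic_rules_rejected():
    rules = [DependencyRule(target="a", antecedents=(("b", "no_or_filled"),)),
             DependencyRule(target="b", antecedents=(("a", "no_or_filled"),))]
    with pytest.raises(ConfigError, match="cycle"):
        toposort_rules(rules)


def test_unknown_and_non_binary_variables_rejected():
    t = make_table({"patient_id": ["p1"], "visit_date": ["2020-01-01"],
                    "weight": [60.0], "flag": ["yes"]},
                   {"weight": "continuous", "flag": "binary"})
    with pytest.raises(ConfigError, match="unknown"):
        apply_rules(t, [DependencyRule(target="flag", antecedents=(("ghost", "yes"),))])
    with pytest.raises(ConfigError, match="non-binary"):
        apply_rules(t, [DependencyRule(target="flag", antecedents=(("weight", "yes"),))])
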