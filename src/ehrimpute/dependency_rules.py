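"""Dependency-based filling of implied "no" values in binary variables.

Many EHR interfaces record follow-up questions only when a gating
question was answered a particular way: if a patient is on antiretroviral
medication but reports no change in regimen, every downstream
"stop/change because of X" field is logically "no" even when the form
left it blank.  This module executes such *declared* dependency chains:
each rule names a target binary variable, a fill value (always "no" in
practice) and an ordered set of antecedent conditions.  A missing target
cell is filled only when every antecedent holds in that row; observed
cells are never touched.

Rules form a DAG over variables (a value filled by one rule may satisfy
the antecedent of a later rule); they are executed in topological order,
which makes the result independent of the order rules were declared in.
"""

from __future__ import annotations

import graphlib
import json
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .data_model import ConfigError, VisitTable

__all__ = ["DependencyRule", "FillLog", "apply_rules", "load_rules", "toposort_rules"]

#: antecedent states: observed "yes"; "no" whether observed or filled by an
#: earlier rule; any non-missing value.
STATES = ("yes", "no_or_filled", "observed")


@dataclass(frozen=True)
class DependencyRule:
    target: str
    antecedents: tuple  # of (variable, state)
    fill_value: str = "no"

    def __post_init__(self):
        for var, state in self.antecedents:
            if var == self.target:
                raise ConfigError(
                    f"rule for {self.target!r} lists itself as an antecedent")
            if state not in STATES:
                raise ConfigError(
                    f"rule for {self.target!r}: unknown antecedent state {state!r}")
        if self.fill_value not in ("yes", "no"):
            raise ConfigError(
                f"rule for {self.target!r}: fill value must be canonical yes/no")


@dataclass
class FillLog:
    """Audit of a dependency-fill pass.

    ``per_rule`` counts cells filled by each rule; ``per_variable``
    records yes/no/missing tallies before and after plus the percent
    increase in filled (non-missing) values, reported both per variable
    and overall.
    """

    per_rule: list = field(default_factory=list)
    per_variable: dict = field(default_factory=dict)
    total_filled: int = 0

    @property
    def overall_percent_increase(self) -> float:
        before = sum(v["observed_before"] for v in self.per_variable.values())
        return 100.0 * self.total_filled / before if before else 0.0

    def to_dict(self) -> dict:
        return {
            "per_rule": [{"target": t, "filled": n} for t, n in self.per_rule],
            "per_variable": self.per_variable,
            "total_filled": self.total_filled,
            "overall_percent_increase": self.overall_percent_increase,
        }


def _rule_graph(rules) -> list:
    """Topological order of variables under antecedent → target edges."""
    ts = graphlib.TopologicalSorter()
    for rule in rules:
        ts.add(rule.target, *(var for var, _ in rule.antecedents))
    try:
        return list(ts.static_order())
    except graphlib.CycleError as exc:
        raise ConfigError(f"dependency rules contain a cycle: {exc.args[1]}") from exc


def toposort_rules(rules) -> list:
    """Order rules so every antecedent's own rule (if any) runs first."""
    order = {name: i for i, name in enumerate(_rule_graph(rules))}
    return sorted(rules, key=lambda r: (order[r.target],))


def apply_rules(table: VisitTable, rules) -> tuple:
    """Apply dependency rules in topological order; returns (table, FillLog).

    A target cell is set to the rule's fill value only when it is missing
    and every antecedent condition holds in that row.  Conditions are
    evaluated against the current state of the table, so a "no" filled by
    an earlier rule satisfies a ``no_or_filled`` antecedent of a later
    one, and the pass is idempotent.
    """
    for rule in rules:
        for name in [rule.target] + [v for v, _ in rule.antecedents]:
            if name not in table.kinds:
                raise ConfigError(f"rule references unknown variable {name!r}")
            if table.kinds[name] != "binary":
                raise ConfigError(
                    f"rule references non-binary variable {name!r} "
                    f"(kind {table.kinds[name]})")

    rules = toposort_rules(rules)
    out = table.copy()
    df = out.df
    log = FillLog()
    targets = {r.target for r in rules}
    before = {
        v: {
            "yes_before": int((df[v] == "yes").sum()),
            "no_before": int((df[v] == "no").sum()),
            "missing_before": int(df[v].isna().sum()),
            "observed_before": int(df[v].notna().sum()),
        }
        for v in targets
    }

    for rule in rules:
        cond = pd.Series(True, index=df.index)
        for var, state in rule.antecedents:
            col = df[var]
            if state == "yes":
                cond &= col == "yes"
            elif state == "no_or_filled":
                cond &= col == "no"
            else:  # observed
                cond &= col.notna()
        fillable = cond & df[rule.target].isna()
        n = int(fillable.sum())
        if n:
            df.loc[fillable, rule.target] = rule.fill_value
        log.per_rule.append((rule.target, n))
        log.total_filled += n

    for v in targets:
        b = before[v]
        obs_b = b["observed_before"]
        filled = int(df[v].notna().sum()) - obs_b
        log.per_variable[v] = {
            **b,
            "yes_after": int((df[v] == "yes").sum()),
            "no_after": int((df[v] == "no").sum()),
            "missing_after": int(df[v].isna().sum()),
            "filled": filled,
            "percent_increase": 100.0 * filled / obs_b if obs_b else float("inf") if filled else 0.0,
        }
    return out, log


def load_rules(path) -> list:
    """Load dependency rules from YAML/JSON.

    Format: a list (or ``{rules: [...]}``) of
    ``{target, fill: "no", when: [{var, is: yes|no_or_filled|observed}]}``.
    Validates the rule schema and that the rules form a DAG.
    """
    with open(path) as fh:
        text = fh.read()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if data is None:
        return []
    if isinstance(data, dict):
        data = data.get("rules", [])
    rules = []
    for item in data:
        if not isinstance(item, dict) or "target" not in item:
            raise ConfigError(f"malformed rule entry: {item!r}")
        when = item.get("when", [])
        antecedents = []
        for clause in when:
            if "var" not in clause or "is" not in clause:
                raise ConfigError(
                    f"rule {item['target']!r}: antecedent needs 'var' and 'is'")
            antecedents.append((clause["var"], str(clause["is"])))
        rules.append(DependencyRule(target=item["target"],
                                    antecedents=tuple(antecedents),
                                    fill_value=str(item.get("fill", "no"))))
    toposort_rules(rules)  # raises on cycles
    return rules
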