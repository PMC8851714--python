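"""Per-stage missingness accounting.

Each stage emits a :class:`StageReport`: per-variable missing counts
before and after, and the percent reduction
``100 * (before - after) / before`` (defined as 0 for variables that
were already complete).  The end-to-end summary mirrors the usual
pre-vs-post view: how many initially incomplete variables improved at
all, and how many improved by 80% or more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .data_model import DataError, missing_counts

__all__ = ["StageReport", "stage_report", "summarize"]


@dataclass
class StageReport:
    stage: str
    per_variable: dict  # name -> {missing_before, missing_after, percent_reduction}
    elapsed: float = 0.0
    extra: dict = field(default_factory=dict)

    @property
    def total_before(self) -> int:
        return sum(v["missing_before"] for v in self.per_variable.values())

    @property
    def total_after(self) -> int:
        return sum(v["missing_after"] for v in self.per_variable.values())

    @property
    def total_percent_reduction(self) -> float:
        b = self.total_before
        return 100.0 * (b - self.total_after) / b if b else 0.0

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "per_variable": self.per_variable,
            "totals": {
                "missing_before": self.total_before,
                "missing_after": self.total_after,
                "percent_reduction": self.total_percent_reduction,
            },
            # wall time is logged, not serialized: identical-seed runs must
            # produce byte-identical report files
            **({"extra": self.extra} if self.extra else {}),
        }


def stage_report(stage: str, before, after) -> StageReport:
    """Compare two same-schema tables; error on schema mismatch."""
    if list(before.variables) != list(after.variables):
        raise DataError("tables have different variable columns")
    mb, ma = missing_counts(before), missing_counts(after)
    per_var = {}
    for name in before.variables:
        b, a = int(mb[name]), int(ma[name])
        if a > b:
            raise DataError(f"missing count increased for {name!r} in stage {stage}")
        per_var[name] = {
            "missing_before": b,
            "missing_after": a,
            "percent_reduction": 100.0 * (b - a) / b if b else 0.0,
            "complete_before": b == 0,
        }
    return StageReport(stage=stage, per_variable=per_var)


def summarize(overall: StageReport) -> dict:
    """Fraction of initially incomplete variables improved, and by ≥80%.

    The "average percent reduction" has two natural readings — the mean
    of per-variable percent reductions, and the overall cell-count
    reduction — so both are reported.
    """
    incomplete = {k: v for k, v in overall.per_variable.items()
                  if v["missing_before"] > 0}
    n = len(incomplete)
    any_red = sum(1 for v in incomplete.values() if v["percent_reduction"] > 0)
    big_red = sum(1 for v in incomplete.values() if v["percent_reduction"] >= 80.0)
    per_var_mean = (sum(v["percent_reduction"] for v in incomplete.values()) / n
                    if n else 0.0)
    return {
        "variables_incomplete": n,
        "variables_with_any_reduction": any_red,
        "fraction_with_any_reduction": any_red / n if n else 0.0,
        "variables_with_reduction_ge_80pct": big_red,
        "mean_percent_reduction_per_variable": per_var_mean,
        "overall_cell_percent_reduction": overall.total_percent_reduction,
    }
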