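"""Stepwise imputation of missing values in longitudinal visit-level EHR data.

Four filling stages — dependency-based "no" fills in binary chains,
per-patient linear interpolation of continuous vitals, chained-equations
multiple imputation with CART conditional models on a patient-level
collapse, and last-date carry-forward — plus missingness-coverage
reporting, a synthetic EHR generator and a random-forest validation
harness.
"""

from .data_model import (ConfigError, DataError, PatientTable, VariableSpec,
                         VisitTable, infer_specs, read_visit_table,
                         write_visit_table)
from .dependency_rules import DependencyRule, FillLog, apply_rules, load_rules
from .interpolation import fit_and_fill, interpolate_table
from .mice_engine import ImputedPatientTable, MiceConfig, fit_cart, mice_impute
from .pipeline import (PipelineConfig, broadcast_to_visits, collapse_to_patient,
                       locf_dates, missingness_report, run_pipeline)
from .report import StageReport, summarize
from .synthetic_data import (GeneratorConfig, GroundTruth, correlated_pair,
                             generate, mask_additional)
from .validation import ForestConfig, ValidationResult, validate

__version__ = "0.1.0"

__all__ = [
    "ConfigError", "DataError", "VisitTable", "PatientTable", "VariableSpec",
    "read_visit_table", "write_visit_table", "infer_specs",
    "DependencyRule", "FillLog", "apply_rules", "load_rules",
    "fit_and_fill", "interpolate_table",
    "MiceConfig", "ImputedPatientTable", "mice_impute", "fit_cart",
    "PipelineConfig", "collapse_to_patient", "broadcast_to_visits",
    "locf_dates", "run_pipeline", "missingness_report",
    "StageReport", "summarize",
    "GeneratorConfig", "GroundTruth", "generate", "mask_additional",
    "correlated_pair",
    "ForestConfig", "ValidationResult", "validate",
    "__version__",
]


def builtin_rules_path() -> str:
    """Path of the bundled ARV-chain dependency rules."""
    from importlib.resources import files
    return str(files("ehrimpute").joinpath("data/arv_rules.yaml"))
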