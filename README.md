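# ehrimpute

Stepwise imputation of missing values in longitudinal, visit-level
electronic health record (EHR) tables.

EHR data collected during routine care — one row per clinic visit, with
clinical, social and economic variables — are rarely complete: providers
enter only the fields relevant to the encounter, and collection standards
vary across sites. In the kind of HIV-care registry that motivates this
package, the large majority of variables contain missing values and many
are missing more than half of their entries, yet the blank cells are often
*informative* (an unticked "changed ARV regimen" box usually means "no")
or strongly structured in time (weight and blood pressure drift slowly per
patient). `ehrimpute` fills such tables with a four-stage procedure that
exploits exactly that structure, at a cost that scales to hundreds of
thousands of visits because the expensive steps are per-patient or
patient-level:

1. **Dependency fill (visit level).** Declared rules of the form
   *on ARV = yes ∧ regimen change = no (observed or filled) ⇒
   stop-reason := no* fill implied "no" values in binary variables.
   Rules are data (YAML), form a DAG, and are applied in topological
   order; a cell filled by one rule may satisfy the antecedent of the
   next.
2. **Per-patient linear interpolation.** For each continuous variable
   with ≥ 10 unique values, an ordinary least-squares line
   `value = a + b·t` (t = days since the patient's first visit) is fitted
   per patient on the observed points; every gap — interior or edge — is
   replaced by the fitted value. Patients with a single observation get a
   constant fill; patients with none are left for stage 3.
3. **Chained-equations imputation (patient level).** The table is
   collapsed to one randomly selected visit per patient, then imputed by
   MICE with classification/regression trees: m = 5 data copies, random
   placeholder initialization, per-variable tree refits in order of
   increasing missingness, donor draws from terminal leaves, and pooling
   by per-cell random selection among the copies. The imputed
   patient-level values are broadcast back into still-missing visit
   cells.
4. **Date carry-forward.** Date variables (which tree models mangle) are
   filled by carrying each patient's last observed date forward; leading
   gaps stay missing.

Every stage reports per-variable missing counts before/after and the
percent reduction `100·(before − after)/before`; observed cells are never
modified, and the whole run is deterministic under a seed. A bundled
synthetic-data generator reproduces the structure this kind of registry
exhibits (overdispersed visit counts, patient-specific affine vitals,
informative ARV-chain blanks, a rare insurance-enrollment outcome driven
by education, illness stage and age), and a random-forest harness
validates imputed tables by predicting that outcome on a held-out 20%
split.

## Worked example

```bash
ehrimpute simulate --n-patients 100 --seed 1 --out visits.csv --truth truth.json
ehrimpute run --input visits.csv --output imputed.csv --report report.json --seed 7
```

which logs, stage by stage:

```
stage dependency_fill  filled   6384 cells in   0.05s
stage interpolation    filled  25727 cells in   0.15s
stage mice_broadcast   filled  54377 cells in   2.14s
stage date_locf        filled   3268 cells in   0.02s
```

On this run 90,405 of the table's cells started missing and 649 remain
(all of them leading date gaps, which carry-forward correctly refuses to
fill backward); all 78 initially incomplete variables were at least
partially filled. The JSON report records, per stage and per variable,
the missing counts and percent reductions. Validating the imputed table
(`ehrimpute validate --input imputed.csv --target nhif_enrolled ...`)
trains the forest on 80% of the visits where enrollment was actually
observed and reports held-out accuracy, F1 on the rare positive class,
the confusion matrix and impurity-decrease feature importances.

The same workflow is available as a library:

```python
from ehrimpute import (GeneratorConfig, PipelineConfig, generate,
                       infer_specs, run_pipeline, builtin_rules_path)
from ehrimpute.dependency_rules import load_rules

masked, truth = generate(GeneratorConfig(n_patients=500, seed=1))
specs = infer_specs(masked)
filled, reports = run_pipeline(masked, load_rules(builtin_rules_path()),
                               specs, PipelineConfig(seed=17))
print(reports[-1].extra)   # pre-vs-post summary
```

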