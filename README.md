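# cvdrisk

A tested pipeline for building and validating a cerebrovascular-disease
(CVD) prevalence risk index on community survey cohorts:

1. **Diagnostic coding** (`cvdrisk.cohort`) — deterministic classification
   of raw survey records (exam, labs, history) into binary risk factors:
   hypertension, diabetes, dyslipidemia, obesity, smoking, drinking,
   exercise sufficiency, age group.
2. **Synthetic cohorts** (`cvdrisk.simulate`) — seeded generation of coded
   cohorts with configurable factor marginals and a log-link risk outcome
   model, plus the deterministic odd/even modeling-validation split.
3. **Poisson regression** (`cvdrisk.regression`) — log-link Poisson GLM on
   the binary outcome (prevalence ratios reported as ORs), Wald chi-square
   tests and 95% CIs, and crude 2x2 chi-square comparisons.
4. **Risk index** (`cvdrisk.index`) — banded conversion of ORs into
   integer risk scores, the exposure-weighted population-average score
   (AROP), individual summed scores (RCI), the ratio R = RCI / AROP, and
   a seven-level risk classification.
5. **Validation** (`cvdrisk.validation`) — cut-point tables over the
   achievable-R grid, Youden-optimal threshold, AUC with DeLong CIs and
   unpaired AUC comparison, Cochran-Armitage trend test, and a
   tie-corrected Wilcoxon rank-sum on ordinal risk levels.
6. **Pipeline & reports** (`cvdrisk.pipeline`, `cvdrisk.cli`) — end-to-end
   orchestration with deterministic CSV/JSON/markdown report rendering.

## CLI

```sh
cvdrisk simulate --n 2138 --seed 1 --out cohort.csv
cvdrisk derive   --records raw.csv --out profiles.csv
cvdrisk fit      --profiles cohort.csv --out fit.json
cvdrisk score    --profiles cohort.csv --out assessments.csv
cvdrisk validate --assessments assessments.csv --out validation.json
cvdrisk run      --n 2138 --seed 1 --format markdown --out report/
```

`run` executes the whole pipeline: simulate (or load `profiles_csv` from a
YAML config) → odd/even split → fit on the modeling half → build the score
model → assess both halves → validate on the validation half → render the
report. Identical seeds give byte-identical reports.

## Library quick start

```python
from cvdrisk import (GeneratorConfig, generate_cohort, split_modeling_validation,
                     fit_poisson_log_binary, build_score_model, assess_profile)
import numpy as np

cohort = generate_cohort(GeneratorConfig(n=2138, seed=1))
modeling, validation = split_modeling_validation(cohort)
y = np.array([p.cvd_case for p in modeling], float)
X = np.array([p.factor_values() for p in modeling], float)
from cvdrisk import MODEL_FACTORS
fit = fit_poisson_log_binary(y, X, names=list(MODEL_FACTORS))
model = build_score_model(fit.or_map())
assessments = [assess_profile(p, model) for p in validation]
```

The shipped defaults (`default_score_model()`) reproduce the published
model: scores 25/10/10/25/10/10 for age ≥60, lack of exercise,
hypertension, diabetes, smoking and family history, AROP = 22.20, and the
achievable cut-point grid including R = 1.80 and 3.15.

## Notes

- The outcome model uses a log link on a binary outcome; for extreme
  covariate patterns exp(linear predictor) can exceed 1, so simulated
  probabilities are capped (default 0.999) and the cap count is reported.
- The exposure registry ships the published reference rates, including the
  physical-exercise rate 0.82, which is the *regular*-exercise proportion
  of the source population even though the scored factor is lack of
  exercise; it is kept as published because the published AROP is only
  reproducible with it.
- Risk-level boundaries are implemented as lower-closed intervals so the
  classification is total (R = 0 is "Very low").
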