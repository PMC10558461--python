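# polyfrac

Matched case–control analysis of polypharmacy and hip-fracture risk in an
elderly claims population: synthetic claims-data generation, cohort
construction with 1:1 age/sex matching, claims-based exposure derivation,
a from-scratch L1-penalized conditional logistic regression solver, and
predictive evaluation (ROC/AUC, Youden cutoff, odds-ratio forests).

## Who this is for

Epidemiologists and biostatisticians who study adverse outcomes of
polypharmacy in administrative claims data. Real claims databases are
proprietary, so the package ships a seeded synthetic generator that
emulates their structure — elderly patients (age ≥ 65, ~71% female, age
peak in the 80s), dated diagnosis events with ICD-10-style codes and a
confirmed flag, dated prescriptions with days supplied — which makes every
stage of the analysis testable end to end without any real data.

## The model

For each case (first confirmed femoral-fracture diagnosis, ICD-10 S72,
inside the study window; diagnosis date = index date) a control of the
same sex and 5-year age band receives a random index date. Exposures at
the index date are 77 covariates: the medication count (maximum number of
distinct drugs active on any day of the 7-day pre-index window, with
prescriptions chained into drug eras across gaps of ≤ 7 days), 60
ATC-style concomitant-medication indicators (episode started before the
index date and running to within 7 days of it), and 16 ICD-10-chapter
comorbidity indicators (confirmed diagnosis, started before the index
date, no end date registered by it).

With pair differences `d_i = x_case,i − x_control,i`, the conditional
likelihood of 1:1 matched pairs reduces to an intercept-free logistic
form, and the penalized estimator solves

```
min_β  Σ_i log(1 + exp(−d_i·β)) + λ‖β‖₁
```

by cyclic coordinate descent with soft-thresholding on the iteratively
reweighted quadratic approximation, warm starts along a geometric λ path
from λ_max = max_j |½ Σ_i d_ij|, and λ chosen by cross-validated
out-of-fold conditional deviance (folds partition pairs). Exponentiated
coefficients are conditional odds ratios. Model discrimination is
summarized by the ROC/AUC (Mann–Whitney with a DeLong-type interval) and
the operating point maximizing the Youden index
(sensitivity + specificity − 1).

## Worked example

```python
import polyfrac as pf

cfg = pf.StudyConfig.from_dict({
    "population": {"n_patients": 4000},
    "cv_folds": 5, "n_lambda": 40, "lambda_min_ratio": 0.02,
}).with_seed(1)
report = pf.run_study(cfg)
payload = report.to_payload()
print(payload["counts"])
print(payload["fits"]["all"]["auc"], payload["fits"]["all"]["n_selected"])
```

prints (seed 1):

```
{'patients': 4000, 'cases_selected': 534, 'pairs': 534, 'unmatched_cases': 0,
 'subjects': 1068, 'early_pairs': 33, 'late_pairs': 501}
0.667 29
```

i.e. 534 matched pairs were formed and the cross-validated conditional
lasso on all 77 covariates kept 29 of them with an in-sample AUC of 0.667
(95% CI 0.634–0.699). The nested variable-set comparison for the same run
is

```
variable_set         n_variables   auc
count                          1   0.556
count+comorbidities           17   0.608
count+medications             61   0.641
all                           77   0.674
```

showing the expected gain from adding comorbidity and medication
indicators to the medication count alone, and the largest selected odds
ratio belongs to anti-Parkinson's drugs (OR 1.47), the strongest planted
association of the default synthetic risk model.

The same pipeline is available from the shell:

```bash
polyfrac run-all --config study.yaml --out results/ --seed 1
polyfrac generate --out data/ --seed 1 --n-patients 4000
polyfrac build-cohort --data data/ --window 2015-01-01:2020-12-31 --seed 1
polyfrac derive --data data/ --grace-days 7 --count-window pre
polyfrac fit --data data/ --n-lambda 40 --folds 5 --seed 1
polyfrac evaluate --data data/ --seed 1
```

## Layout

- `src/polyfrac/synth.py` — seeded synthetic population, claims streams, outcomes
- `src/polyfrac/cohort.py` — case/control selection and 1:1 matching
- `src/polyfrac/exposure.py` — drug eras, exposure flags, medication count, descriptive table
- `src/polyfrac/model.py` — conditional logistic likelihood, lasso path, CV, Newton MLE
- `src/polyfrac/evaluate.py` — ROC/AUC, Youden, forests, nested comparison, stepwise, external validation
- `src/polyfrac/pipeline.py` — one-config orchestration with derived stage seeds
- `docs/methods.md` — modelling assumptions, defaults, and limitations
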