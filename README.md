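# readmit

Predicting 30-day all-cause hospital readmission from linked administrative
health data, with machine-learned medical-code embedding features alongside
a classical manually engineered battery.

Unplanned readmissions are among the costliest recurring events in a health
system, and the standard bedside instrument — the LACE index (Length of
stay, Acuity, Charlson comorbidity, Emergency visits) — leaves much of the
predictable risk on the table.  This package implements the full analysis a
readmission-modeling study runs over population-level linked tables
(hospital discharge abstracts, ambulatory visits, physician claims,
prescriptions, labs): care-episode linking and index-cohort construction,
Charlson/LACE scoring, windowed utilization features, *patient sentences* of
chronologically ordered medical codes embedded with CBOW Word2Vec and summed
over the last 25 codes, and a cross-validated evaluation grid comparing
logistic regression and gradient boosting over feature sets against the
LACE-only baseline.  Because such data are access-restricted, a seeded
synthetic generator with a planted latent-risk structure stands in for the
real tables, making every stage runnable and testable end to end.

## The model

For patient *i* with index episode discharged at time *t*, the package
computes

* manual features `m_i`: age, sex, disposition, length of stay, windowed
  counts of prior discharges, in-hospital days, ED and outpatient visits,
  physician claims and paid amounts, prescriptions, chronic-condition flags,
  a two-year Charlson score, simplified lab categories;
* embedding features `w_i = sum_{j in last-25 codes} v(c_ij)`, where
  `v : code -> R^d` is a CBOW embedding trained on patient sentences of all
  normalized codes dated up to each patient's own index discharge;
* the LACE score `L_i` in 0–19.

Models `P(readmit within 30d | features)` are fit with logistic regression
and gradient boosting over {manual, embedding, both}, plus a tuned booster
(learning rate 0.01, depth 8, 1000 rounds) and a univariate logistic model
on `L_i`.  Evaluation follows an 11-part patient-level split: ten parts
drive 10-fold cross-validation (embeddings retrained per training split),
the eleventh is an untouched holdout.  Reported: per-fold and holdout AUC,
sensitivity at specificity 0.75, continuous NRI with bootstrap CIs, and
Bonferroni-adjusted paired t-tests on fold AUCs.

## Worked example

Run the numbered analysis drivers over one 10,000-patient synthetic
population (artifacts land in `results/study/`):

```bash
cd analysis
python 01_simulate.py && python 02_cohort.py && python 03_features.py
python 04_embeddings.py && python 05_models.py
```

Selected output (seed 1):

```
cohort: 9738 patients, one index episode each
30-day readmission rate: 8.58%

                   not readmitted  readmitted
n_discharges_730d            1.23        1.80
ed_visits_182d               0.31        0.37
rx_records_730d              1.98        2.55
charlson_730d                1.22        1.42
lace_score                   6.07        6.37

  nearest to I10: I50 (0.96), E11 (0.96), ...
  nearest to 401: 250 (0.92), 428 (0.88), ...

            model         features               name  cv_auc_mean  test_auc
         logistic           manual          lr_manual       0.6716    0.6602
         logistic        embedding             lr_w2v       0.6737    0.6956
         logistic manual+embedding        lr_combined       0.6918    0.6933
gradient_boosting           manual         gbm_manual       0.6366    0.6387
gradient_boosting        embedding            gbm_w2v       0.6304    0.6469
gradient_boosting manual+embedding       gbm_combined       0.6745    0.6726
gradient_boosting manual+embedding gbm_tuned_combined       0.6759    0.6946
         logistic             lace            lr_lace       0.5380    0.5186

  gbm_manual->gbm_combined: NRI 0.3120 [0.0795, 0.5476]
```

Reading it: readmitted patients show heavier prior utilization and higher
LACE scores — the planted risk structure surfacing through the manual
battery — and the embedding has learned clinically coherent neighbourhoods
(the hypertension code `I10` sits next to heart failure `I50` and diabetes
`E11`; the claim code `401` next to `250` and `428`).  Every learned model
beats the LACE baseline (CV AUC 0.538) by 9–15 points, combining manual and
embedding features helps both families, and no model exceeds the latent-risk
oracle for this population (AUC 0.749), the ceiling the generator defines.
Absolute numbers are properties of the synthetic population, not of any real
health system.

The same pipeline is scriptable from the shell:

```bash
readmit run-all --config configs/default.yaml --seed 1 --out results/run1
```

which writes `cohort.csv`, `features.csv`, `sentences.txt`,
`embeddings.tsv`, `report.{json,csv}`, per-model ROC dumps, and a
`run_manifest.json` that byte-reproduces on rerun.

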