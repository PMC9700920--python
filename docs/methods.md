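# Methods

`readmit` implements an end-to-end 30-day hospital-readmission prediction
analysis over linked administrative health data: cohort construction from
discharge abstracts, a manually derived feature battery with Charlson and
LACE scoring, machine-learned features built from CBOW embeddings of medical
codes, and a cross-validated model-comparison protocol.  Because the kind of
population-level linked data this analysis targets is access-restricted
everywhere it exists, the package ships a synthetic-data generator that
emulates the relevant structure; every empirical claim below is about what
the pipeline computes on that generator.

## The prediction problem

One *index* hospital episode is chosen per patient; the outcome is all-cause
readmission — any new hospital episode admitting within the half-open window
`(discharge, discharge + 30 days]`.  An admission exactly 30 days after
discharge counts; a same-day re-entry does not, because episode linking has
already merged it into the index episode as a continuation of care.
Prediction happens at discharge: features may use anything dated up to the
index discharge and nothing after it.

## Synthetic data generator

Each patient carries a latent standard-normal risk score `z` that drives
everything jointly:

* **Utilization.** Event counts per table are Poisson with per-year rates
  `share_table x mean_events_per_patient_year x exp(0.3 z)` (default 6
  events/patient-year split across hospitalizations 10%, ambulatory 28%,
  claims 36%, prescriptions 16%, labs 10%), so high-risk patients use more
  care — the pattern the manual utilization features are designed to read.
* **Code content.** Synthetic but format-faithful vocabularies (`K65`-style
  diagnoses, `1.SQ.52`-style dotted procedures, `J01DH`-style ATC codes) are
  partitioned into clusters; each patient draws ~70% of codes from a home
  cluster whose index tilts with `z`.  This plants the co-occurrence
  structure CBOW is supposed to recover and gives embedding features real
  signal.
* **Chronic conditions.** Hypertension, diabetes, heart failure and asthma
  are assigned at realistic prevalences (29/14/6/2%) with a `0.5 z` log-odds
  tilt, leaving both hospital diagnosis codes and physician-claim codes so
  the case-definition rules fire.
* **Outcome.** After each episode's final discharge a readmission is planted
  with probability `logistic(logit(base_rate) + risk_effect x z)` (defaults
  0.06 and 1.0), admitting 2–30 days later.  Background admissions are
  spaced more than 30 days after any prior discharge, so a realized 30-day
  readmission occurs iff planted.

One design choice deserves emphasis: **planted readmission records carry a
psychiatric primary diagnosis.**  Under the cohort rules this makes them
count as (all-cause) outcomes while never being index candidates.  Without
this, outcome admissions join the candidate pool and a patient's candidate
count becomes coupled to their past outcome coins; empirically that coupling
put the selected-episode outcome rate anywhere between 0.3% and 30% depending
on candidate count and let models "predict" a nominally null outcome.  With
it, every candidate's outcome is one independent logistic coin: at
`risk_effect = 0` the realized rate matches the base rate (0.0597 vs 0.06 at
n = 10,000) and the true latent risk scores AUC 0.504 against realized
labels.

The observation window is 2011–2017 with the index window fixed to the two
calendar years before the final year (2015–2016), so every index episode has
a full four-year lookback and a full year of outcome follow-up; the final
year exists only to host outcomes.  Every patient is forced to have at least
one admission in the index window, mirroring a population defined by "was
discharged during the index years".

What the generator does **not** emulate: realistic disease-specific
epidemiology, seasonality, coding drift, regional variation, death after
discharge, or out-of-province migration.  Passing tests therefore show the
pipeline's machinery is correct and that it recovers planted structure — not
that any particular AUC level transfers to real administrative data.

## Cohort construction

Discharge records are linked into episodes when a record admits at most one
day after the previous discharge or the previous record's disposition is a
transfer code (01/02/03).  Index candidacy then excludes, in order:
in-hospital deaths (07), invalid patient ids and out-of-province patients;
transfer dispositions; and psychiatric primary diagnoses (F00–F99 except the
substance-use block F10–F19).  One candidate per patient is selected
uniformly at random (seeded; invariant to row order), labeled, and the
cohort is split patient-level into 11 near-equal parts: part 0 is the
holdout, parts 1–10 the CV folds.

## Features

All windows anchor at the index admission and end the day before it
(6 months = 182 days, 1/2/3/4 years = 365/730/1095/1460), except
index-episode features (member records) and the Charlson score, whose
two-year lookback includes the index episode and ends at discharge.  Both
1-year and 2-year variants of the hospital-utilization and ambulatory-visit
counts are emitted since reasonable definitions differ.  Lab results are
simplified to the last value per test within two years, categorized
low/normal/high against the reference range, with explicit `missing`.
Charlson uses the standard ICD-10 prefix mapping with the original integer
weights and three supersession pairs (shipped as `data/charlson_map.csv`);
LACE uses the published point bins (`data/lace_points.csv`), with the
emergent-admission flag of the index episode as the acuity component and
emergency ambulatory visits in the prior 182 days as the E component.
Chronic conditions default to "1 hospital code or 2 claims within 2 years",
configurable per condition.

## Code embeddings

Patient sentences concatenate every normalized code (uppercased, periods and
whitespace stripped) dated up to the index discharge, sorted by date with
ties broken by a fixed source order then lexicographically.  An emergent
hospital admission also contributes an event token.

The CBOW trainer is implemented in numpy: negative sampling (5 noise draws
from the unigram distribution to the 3/4 power), frequent-token subsampling
at threshold 1e-3, mini-batches of 512 with a linearly decaying learning
rate from 0.025, and mean-of-context input updates.  All randomness flows
from one seeded generator, so a fixed config reproduces identical vectors.
Package defaults are 100 dimensions, window 5, min_count 5, 10 epochs; the
bundled analyses use 32 dimensions and 5 epochs, which at these corpus sizes
(~60–80 tokens per patient) already separate the planted clusters cleanly
and keep 11 retrainings per experiment affordable on one core.

A patient's feature vector is the sum of the vectors of their last K = 25
in-vocabulary codes (all codes when fewer).  Out-of-vocabulary tokens are
skipped without consuming a slot, which keeps the identity "same last-K
in-vocabulary sequence, same vector" exact.

Embeddings are retrained on each CV training split (and on all ten CV parts
for the holdout model), so no evaluation patient's sentence influences the
features they are scored with.  A corpus-wide embedding (still excluding the
holdout) is available as `embedding_scope: global`.

## Models and evaluation

The default grid crosses logistic regression and gradient boosting with
{manual, embedding, manual+embedding} features, adds a tuned gradient
booster (learning_rate 0.01, max_depth 8, 1000 rounds) on the combined set,
and a univariate logistic baseline on the integer LACE score — eight rows.
Logistic models standardize inputs.  The gradient-boosting family is backed
by scikit-learn's histogram-based implementation, the library's modern GBM;
the classic exact-split variant is selectable per model
(`params: {implementation: exact}`) but is roughly fifty times slower at
these problem sizes on one core, which rules it out for the bundled
experiment scales.

Metrics: per-fold and holdout AUC; sensitivity at the most permissive actual
threshold whose specificity is still at least the target (0.75 by default;
no ROC interpolation); category-free NRI between model pairs with 95%
patient-level bootstrap percentile CIs (1,000 resamples by default); and
two-sided paired t-tests on aligned fold AUCs, Bonferroni-adjusted over all
pairs, with zero-variance differences handled as p = 1 (identical folds) or
p = 0 (constant nonzero offset).

## Numerical and statistical notes

* Every stage seed derives from one global seed and is recorded in the run
  manifest; reruns of a config byte-reproduce reports.
* The bundled experiments run at n = 5,000–20,000 patients.  At n = 5,000
  (~280 events) a model's mean CV AUC under a true null is unbiased but has
  dataset-level sd of roughly 0.02 — calibration checks at this scale
  therefore average over replicate populations rather than trusting a single
  draw.
* Degenerate inputs are defined errors, not silent behavior: single-class
  folds, empty embedding corpora, negative LACE inputs, cohorts smaller than
  the part count, and windows shorter than two years all raise.

## Limitations

The generator's independence structure (outcome coins iid given the latent
risk) is cleaner than reality, where readmissions cascade; absolute AUC
levels on synthetic data say nothing about real-data performance.  The
Charlson and chronic-condition code lists are standard operationalizations,
not validated against chart review.  Death after discharge is not modeled,
so no competing-risk censoring exists.
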