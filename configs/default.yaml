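synth:
  n_patients: 1000
  start_date: '2011-01-01'
  end_date: '2017-12-31'
  index_years: 2
  base_readmit_rate: 0.06
  risk_effect: 1.0
  n_code_clusters: 10
  codes_per_cluster: 30
  mean_events_per_patient_year: 6.0
  seed: 0
  female_frac: 0.62
  ed_admit_frac: 0.88
  out_of_province_frac: 0.005
  psych_primary_frac: 0.04
  chain_frac: 0.05
  utilization_coef: 0.3
  cluster_risk_coef: 1.5
embedding:
  dimension: 100
  window: 5
  min_count: 5
  epochs: 10
  negative: 5
  learning_rate: 0.025
  min_learning_rate: 0.0001
  subsample: 0.001
  batch_size: 512
  seed: 0
k_last: 25
embedding_scope: per_split
include_event_tokens: true
model_grid: default
target_specificity: 0.75
nri_bootstrap: 1000
seed: 0
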