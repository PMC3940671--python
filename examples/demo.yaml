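# Full-pipeline demo: simulate a 36-subject cohort under the default
# additive RT model, preprocess, score with both methods, run the three
# factorial analyses, and estimate reliability.
seed: 42
simulate:
  n_subjects: 36
  n_blocks: 3
  alerting_sd_ms: 15.0
  orienting_sd_ms: 15.0
  conflict_sd_ms: 20.0
preprocess: {}
score:
  method: both
  normalization: raw
analyze:
  normalization: raw
reliability:
  n_perm: 200
  normalization: raw
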