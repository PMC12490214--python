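# Desk-scale end-to-end experiment: ~3,000 patients, a small model,
# minutes on one CPU.  Run with:
#   pancrisk run --config examples/quickstart.yaml --outdir experiments/quickstart
sim:
  n_patients: 3000
  target_case_fraction: 0.08
  visit_rate: 6.0
  record_span_years: [2.0, 10.0]
  planted_risk_codes: [["A20", 8.0], ["A45", 8.0], ["M012", 8.0], ["M030", 8.0]]
  seed: 7

prep:
  exclusion_months: 3
  max_len: 48
  censoring: zero_fill

model:
  L: 1
  H: 2
  d: 16

train:
  lr: 0.01
  epochs_max: 8
  batch_size: 128
  seed: 7

eval:
  horizon_months: 36
  top_n: 50
  seed: 7

attribution:
  k: 50
  steps: 32
  seed: 7
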