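# Bundled demo: synthetic cohort with two planted signals, all stages on.
# Run with:  protclock run-all --config examples/demo_config.yaml --seed 1 --outdir demo_run
seed: 1
synth:
  scenario: classification   # cis-pQTL + widespread trans factor
  n_samples: 3000
  n_proteins: 300
  n_variants: 500
stages:
  simulate: true
  preprocess: true
  clock: true
  importance: true
  assoc: true
  classify: true
  outcomes: true
  mr: true
clock:
  alpha: 0.5
  n_folds: 10
thresholds:
  genome_wide_p: 5.0e-8
  min_maf: 0.001
  max_missing: 0.10
  r2_max: 0.05
mr:
  n_instruments: 50
  true_slope: 0.3
  pleiotropy_intercept: 0.02
  se_scale: 0.05
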