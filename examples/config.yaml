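# Example run configuration: simulate a cohort and run the full pipeline.
outdir: runs/demo
seed: 0
# no `inputs:` block -> the simulate stage generates the cohort under
# <outdir>/data (supply paths here to analyse your own data instead)
generator: {}          # defaults: 20000 genes, 8 lines x 2 reps, 100 patients
normalize: false       # synthetic data is already on a log scale
filter:
  expressed_fraction: 0.33
  n_variable: 5000
lambda_grid: {min: 1.0e-3, max: 1.0e5, num: 50}
top_k: 25
concordance:
  min_self_corr: 0.5
  min_mutual_corr: 0.5
standardization: target
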