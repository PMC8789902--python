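# Example pipeline configuration for `edna-occ run --config ...`
seed: 2018
out_dir: results/pipeline_run
simulate:
  S: 500
  M: 1
  K: 12
  theta11: 0.948
  theta10: 0.015
  p11: 0.808
  p10: 0.020
  covariates:
    n_continuous: 3
    categorical:
      landcover: 5
  # intercept; x1..x3; 4 land-cover contrasts vs the baseline level
  beta: [-1.5, 0.8, -0.4, 0.0, 0.3, -0.3, 0.2, 0.0]
prep:
  threshold: 0.7
model:
  n_burn: 1000
  n_iter: 2000
  n_thinned_draws: 100
gof:
  n_repeats: 100
  plot: true
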