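phantom:
  n_patients: 8
  n_controls: 8
  shape: [40, 40, 28]
  seed: 7
enet:
  alpha_grid: [0.5]
  n_lambda: 10
  lambda_decades: 2
  tol: 0.001
  max_iter: 500
n_boot: 1000
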