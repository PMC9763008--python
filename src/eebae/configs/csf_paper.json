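{
  "model": "csf",
  "param_ranges": {
    "gamma_max": [2, 2000],
    "f_max": [0.2, 100],
    "beta1": [2, 128],
    "delta1": [0.2, 3]
  },
  "param_grid_sizes": {"gamma_max": 20, "f_max": 20, "beta1": 20, "delta1": 20},
  "stim_ranges": {
    "log_f": [-0.6989700043360187, 1.5563025007672873],
    "log_c": [-3.0, 0.0]
  },
  "stim_grid_sizes": {"log_f": 20, "log_c": 20},
  "truth": {"gamma_max": 100, "f_max": 2.5, "beta1": 2.5, "delta1": 0.25},
  "policy": {"kind": "ee", "epsilon": 1.5, "trials": 250},
  "replications": 5000,
  "seed": 20221212,
  "mu": 0.04,
  "likelihood_dtype": "float32"
}
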