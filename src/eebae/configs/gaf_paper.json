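{
  "model": "gaf",
  "param_ranges": {"t_cr": [5, 10], "sigma": [1, 4]},
  "param_grid_sizes": {"t_cr": 20, "sigma": 20},
  "stim_ranges": {"gap": [4, 12]},
  "stim_grid_sizes": {"gap": 25},
  "truth": {"t_cr": 7.3, "sigma": 2.2804},
  "policy": {"kind": "ee", "epsilon": 6.4, "trials": 300},
  "replications": 5000,
  "seed": 20221212
}
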