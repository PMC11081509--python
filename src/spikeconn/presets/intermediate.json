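{
  "name": "intermediate",
  "target": {
    "burst_rate_hz": 0.4,
    "mean_rate_hz": 1.1,
    "cv": 0.4
  },
  "network": {
    "n": 300,
    "frac_exc": 0.5,
    "p_conn": 0.05
  },
  "input": {
    "mode": "bursty",
    "n_input_units": 30,
    "rate_hz": 2.0,
    "burst_rate_hz": 0.4,
    "burst_width_ms": 120.0,
    "burst_amplitude_hz": 60.0,
    "burst_min_gap_ms": 500.0,
    "p_input_conn": 0.1,
    "input_weight_scale": 0.15
  },
  "initial_noise": {
    "mu_noise": -0.044,
    "sigma_noise": 0.1
  }
}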