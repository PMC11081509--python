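{
  "name": "poisson_8020",
  "target": {"burst_rate_hz": 0.0, "mean_rate_hz": 1.5, "cv": 0.2},
  "network": {"n": 300, "frac_exc": 0.8, "p_conn": 0.02},
  "input": {"mode": "poisson", "n_input_units": 30, "rate_hz": 2.0,
            "p_input_conn": 0.1, "input_weight_scale": 0.15},
  "initial_noise": null
}
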