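{
  "population": {
    "n_normal": 5000,
    "n_cardiomegaly": 2517,
    "seed": 1
  },
  "observers": [
    {"observer_id": "obs1", "relative_bias": 0.0, "relative_sd": 0.0107, "seed": 2},
    {"observer_id": "obs2", "relative_bias": 0.0162, "relative_sd": 0.0184, "seed": 3}
  ],
  "ai_model": {"seed": 4},
  "accept_tol": 0.018
}
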