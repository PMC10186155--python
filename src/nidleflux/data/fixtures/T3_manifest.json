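{
  "condition_id": "c1",
  "expected_q": 15.0,
  "expected_z": 1,
  "model_id": "T3",
  "mu": 5.0,
  "n_ra": 1,
  "n_ri": 1,
  "name": "T3",
  "uptake_bound": 10.0
}
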