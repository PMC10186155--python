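{
  "condition_id": "c1",
  "expected_q": 15.0,
  "expected_z": 3,
  "model_id": "T2",
  "mu": 5.0,
  "n_ra": 4,
  "n_ri": 0,
  "name": "T2",
  "uptake_bound": 10.0
}
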