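{
 "subtype": "a4b2",
 "EC50_uM": 30.0,
 "alpha": 3.0,
 "n_a": 1.05,
 "IC50_uM": 0.061,
 "n_d": 0.5,
 "tau_a_ms": 5.0,
 "K_tau_uM": 0.11,
 "n_tau": 3.0,
 "tau_max_min": 10.0,
 "tau_0_ms": 500.0,
 "eta": 0.0
}
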