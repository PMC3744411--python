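{
 "subtype": "a7",
 "EC50_uM": 80.0,
 "alpha": 2.0,
 "n_a": 1.73,
 "IC50_uM": 1.3,
 "n_d": 2.0,
 "tau_a_ms": 5.0,
 "K_tau_uM": 1.73,
 "n_tau": 2.0,
 "tau_max_min": 2.0,
 "tau_0_ms": 50.0,
 "eta": 0.0
}
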