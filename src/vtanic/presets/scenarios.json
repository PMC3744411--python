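{
 "direct_stimulation": {
  "r": 0.8,
  "nu_ach_uM": 0.1,
  "nu_glu": 0.2,
  "nic_duration_s": 600.0
 },
 "disinhibition": {
  "r": 0.2,
  "nu_ach_uM": 1.77,
  "nu_glu": 0.2,
  "nic_duration_s": 120.0
 },
 "in_vitro_ipsc": {
  "r": 0.5,
  "nu_ach_uM": 0.266587,
  "nu_glu": 0.0,
  "nic_duration_s": 120.0,
  "glu_blocked": true
 },
 "in_vitro_epsc": {
  "r": 0.5,
  "nu_ach_uM": 0.266587,
  "nu_glu": 0.000376782,
  "nic_duration_s": 120.0,
  "gaba_blocked": true
 }
}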