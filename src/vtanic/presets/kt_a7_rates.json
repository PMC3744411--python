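{
 "comment": "Katz-Thesleff cycle rates for the alpha7 receptor, least-squares fitted to the two-gate open-fraction trace for a 1 s, 100 uM agonist pulse (synthetic fit artifact, regenerable with fit_kt_rates). Units: k_on, k_bind per uM per s; others per s.",
 "rates": {
  "k_on": 1.190657720753982,
  "k_off": 83.52477747621518,
  "k_des_b": 20.6914282596557,
  "k_res_b": 1.967321291435426e-06,
  "k_unbind": 424.3756867144953,
  "k_bind": 0.19887689346375642,
  "k_rec": 0.0021757202609403287,
  "k_des_u": 1.1950563467713054e-05
 },
 "fit": {
  "conc_uM": 100.0,
  "pulse_s": 1.0,
  "washout_s": 1.0,
  "dt_s": 0.001,
  "max_abs_dev": 1.7e-05
 },
 "hill_map": {
  "reference_uM": 100.0,
  "n": 2.0
 },
 "validation_max_abs_dev": {
  "13.6": {
   "conc_kt": 1.8496,
   "max_abs_dev": 0.025543
  },
  "35.4": {
   "conc_kt": 12.5316,
   "max_abs_dev": 0.077895
  },
  "100.0": {
   "conc_kt": 100.0,
   "max_abs_dev": 1.7e-05
  },
  "258.7": {
   "conc_kt": 669.2569,
   "max_abs_dev": 0.449708
  }
 }
}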