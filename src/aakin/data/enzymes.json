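{
 "cysRS": {
  "class": "I",
  "sites": 1,
  "variant": "class1_monomer",
  "targets": {
   "pp_kcat": 85.0,
   "pp_km_aa": 27.0,
   "pp_km_atp": 279.0,
   "aa_kcat": 2.96,
   "aa_km_aa": 16.0,
   "aa_km_trna": 1.05,
   "k_tran": 14.9,
   "k_chem": 15.2,
   "burst": true
  },
  "fitted_observables": {
   "pp_kcat": 85.0832,
   "pp_km_aa": 26.9149,
   "pp_km_atp": 277.9519,
   "aa_kcat": 2.7819,
   "aa_km_trna": 0.9997,
   "aa_km_aa": 14.629,
   "k_tran": 14.6389,
   "k_chem": 11.9886,
   "burst": true
  },
  "fit_seed": 1
 },
 "hisRS": {
  "class": "II",
  "sites": 2,
  "variant": "class2_flipflop",
  "targets": {
   "pp_kcat": 130.0,
   "pp_km_aa": 37.0,
   "pp_km_atp": 498.0,
   "aa_kcat": 7.2,
   "aa_km_aa": 7.0,
   "aa_km_trna": 0.44,
   "k_tran": 18.8,
   "burst": false
  },
  "fitted_observables": {
   "pp_kcat": 129.7742,
   "pp_km_aa": 37.1835,
   "pp_km_atp": 499.3172,
   "aa_kcat": 7.2561,
   "aa_km_trna": 0.4298,
   "aa_km_aa": 6.9804,
   "k_tran": 21.5814,
   "k_chem": 7.9313,
   "burst": false
  },
  "fit_seed": 5
 }
}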