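{
 "table_id": "centiles_la_max_volume_boys_bsa",
 "kind": "centile_table",
 "covariate": "bsa_m2",
 "units": "mL",
 "population": "children",
 "title": "Maximal LA volume (biplane area-length) by BSA in boys: printed centiles"
}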