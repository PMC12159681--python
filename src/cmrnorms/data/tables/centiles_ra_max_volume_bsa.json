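{
 "table_id": "centiles_ra_max_volume_bsa",
 "kind": "centile_table",
 "covariate": "bsa_m2",
 "units": "mL",
 "population": "children",
 "title": "Maximal RA volume (monoplane area-length) by BSA in boys and girls: printed centiles"
}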