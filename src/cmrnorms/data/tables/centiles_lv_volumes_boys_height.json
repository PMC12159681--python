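{
 "table_id": "centiles_lv_volumes_boys_height",
 "kind": "centile_table",
 "covariate": "height_cm",
 "units": "mL",
 "population": "children",
 "title": "LV volumes by body height in boys (papillary muscles excluded): printed centiles"
}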