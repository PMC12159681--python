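{
 "table_id": "lv_athletes_mass_conv",
 "kind": "ranges",
 "title": "Indexed LV parameters in elite adult athletes, bSSFP; papillary muscles in LV mass",
 "population": "adult athletes",
 "convention": "papillary_in_mass",
 "notes": "Single-study mean +/- 2SD ranges; >18 training hours/week."
}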