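{
 "table_id": "lv_athletes_volume_conv",
 "kind": "ranges",
 "title": "LV parameters in adult athletes, bSSFP; papillary muscles in LV volume",
 "population": "adult athletes",
 "convention": "papillary_in_volume",
 "notes": "Single-study mean +/- 2SD ranges; regular = 9-18 h sport/week, elite = >18 h/week."
}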