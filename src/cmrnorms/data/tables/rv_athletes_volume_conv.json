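{
 "table_id": "rv_athletes_volume_conv",
 "kind": "ranges",
 "title": "RV parameters in adult athletes, bSSFP; papillary muscles in RV volume",
 "population": "adult athletes",
 "convention": "papillary_in_volume",
 "notes": "Single-study mean +/- 2SD ranges."
}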