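{
 "table_id": "lv_adult_bssfp_mass_conv",
 "kind": "ranges",
 "title": "LV volume, mass and function in adults, bSSFP; papillary muscles in LV mass",
 "population": "adults",
 "convention": "papillary_in_mass",
 "notes": "Pooled multi-study estimates; the LVCI row for women is a median [IQR] and is excluded from z-score computation."
}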