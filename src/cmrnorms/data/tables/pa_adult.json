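{
 "table_id": "pa_adult",
 "kind": "ranges",
 "title": "Main pulmonary artery dimensions and distension in adults (all-age rows)",
 "population": "adults",
 "notes": "Single-study mean +/- 2SD, cross-sectional bSSFP."
}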