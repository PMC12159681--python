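{
 "table_id": "ecv_children",
 "kind": "ranges",
 "title": "Extracellular volume fraction in children",
 "population": "children",
 "notes": "Single study, mean +/- 2SD."
}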