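{
 "table_id": "t1_native_children",
 "kind": "ranges",
 "title": "Native myocardial T1 time in children (septal ROI, mid-ventricular SAX)",
 "population": "children",
 "notes": "Per-study mean +/- 2SD; rows differ by field strength, vendor and sequence and must be matched on the technique tag."
}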