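{
 "table_id": "t2_children",
 "kind": "ranges",
 "title": "Myocardial T2 time in children (septal ROI, mid-ventricular SAX)",
 "population": "children",
 "notes": "Per-study mean +/- 2SD."
}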