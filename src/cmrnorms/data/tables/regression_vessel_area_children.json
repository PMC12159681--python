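{
 "table_id": "regression_vessel_area_children",
 "kind": "regression",
 "population": "children",
 "title": "Great-vessel cross-sectional areas in children: predicted area a + b*BSA (no residual SD published, prediction only)"
}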