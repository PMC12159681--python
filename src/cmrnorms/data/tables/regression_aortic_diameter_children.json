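{
 "table_id": "regression_aortic_diameter_children",
 "kind": "regression",
 "population": "children",
 "title": "Aortic diameters in children: predicted diameter a + b*sqrt(BSA) and SD of residuals"
}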