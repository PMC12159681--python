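{
 "table_id": "lms_aortic_area_children",
 "kind": "lms",
 "parameter_id": "aortic_area",
 "covariate": "age_years",
 "units": "mm^2",
 "population": "children",
 "site_column": true,
 "title": "Aortic cross-sectional area in children: LMS parameters by age, four sites"
}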