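{
 "table_id": "lms_aortic_pwv_children",
 "kind": "lms",
 "parameter_id": "aortic_pwv",
 "covariate": "age_years",
 "units": "m/s",
 "population": "children",
 "title": "Aortic arch pulse wave velocity in children: LMS parameters by age"
}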