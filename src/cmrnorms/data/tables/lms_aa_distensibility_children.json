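{
 "table_id": "lms_aa_distensibility_children",
 "kind": "lms",
 "parameter_id": "aa_distensibility",
 "covariate": "age_years",
 "units": "10^-3 mmHg^-1",
 "population": "children",
 "title": "Ascending-aorta distensibility in children: LMS parameters by age"
}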