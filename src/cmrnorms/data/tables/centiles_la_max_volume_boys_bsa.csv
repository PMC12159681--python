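parameter_id,sex,covariate_value,c5,c10,c25,c50,c75,c90,c95
la_max_vol,male,0.8,16,17,19,22,26,29,31
la_max_vol,male,0.9,17,18,21,25,29,32,35
la_max_vol,male,1.0,18,20,23,27,32,36,39
la_max_vol,male,1.1,19,21,25,30,36,41,44
la_max_vol,male,1.2,21,23,28,33,40,46,49
la_max_vol,male,1.3,22,25,30,37,44,51,55
la_max_vol,male,1.4,24,28,34,41,49,56,61
la_max_vol,male,1.5,27,30,37,45,54,62,67
la_max_vol,male,1.6,30,34,41,50,59,68,74
la_max_vol,male,1.7,33,38,46,55,65,75,80
la_max_vol,male,1.8,38,43,51,61,71,81,87
la_max_vol,male,1.9,44,49,57,67,78,88,94
la_max_vol,male,2.0,50,56,64,75,85,95,101
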