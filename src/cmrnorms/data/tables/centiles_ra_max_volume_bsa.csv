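parameter_id,sex,covariate_value,c5,c10,c25,c50,c75,c90,c95
ra_max_vol,male,0.8,14,16,20,25,30,36,40
ra_max_vol,male,0.9,16,18,22,27,33,39,43
ra_max_vol,male,1.0,17,19,24,30,37,43,47
ra_max_vol,female,1.0,10,13,18,23,29,34,37
ra_max_vol,male,1.1,18,21,27,33,40,47,51
ra_max_vol,female,1.1,13,16,22,27,33,38,42
ra_max_vol,male,1.2,18,23,29,37,44,51,55
ra_max_vol,female,1.2,17,20,26,32,38,43,47
ra_max_vol,male,1.3,19,24,33,41,49,56,60
ra_max_vol,female,1.3,20,24,29,36,42,48,52
ra_max_vol,male,1.4,21,27,36,45,54,61,65
ra_max_vol,female,1.4,23,27,33,40,47,53,57
ra_max_vol,male,1.5,23,30,40,51,60,67,71
ra_max_vol,female,1.5,27,31,37,44,51,58,62
ra_max_vol,male,1.6,26,33,45,56,66,74,78
ra_max_vol,female,1.6,30,34,41,48,56,63,67
ra_max_vol,male,1.7,29,38,50,62,73,81,85
ra_max_vol,female,1.7,33,37,45,53,60,68,72
ra_max_vol,male,1.8,34,43,56,69,80,89,94
ra_max_vol,female,1.8,36,41,48,57,65,73,77
ra_max_vol,male,1.9,39,48,63,77,89,98,103
ra_max_vol,female,1.9,39,44,52,61,70,78,82
ra_max_vol,male,2.0,44,55,71,86,98,107,113
ra_max_vol,female,2.0,42,47,56,65,74,83,88
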