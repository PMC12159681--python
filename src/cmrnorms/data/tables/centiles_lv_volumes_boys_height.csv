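parameter_id,sex,covariate_value,c5,c10,c25,c50,c75,c90,c95
lvedv,male,110,45,47,50,54,59,64,68
lvesv,male,110,14,14,16,18,21,24,26
lvsv,male,110,27,29,33,37,41,45,48
lvedv,male,120,52,55,59,64,70,76,80
lvesv,male,120,16,17,19,22,25,29,31
lvsv,male,120,31,34,38,42,48,52,55
lvedv,male,130,61,64,69,75,82,90,95
lvesv,male,130,19,21,23,26,30,35,38
lvsv,male,130,36,39,44,49,55,61,64
lvedv,male,140,71,75,81,89,97,107,112
lvesv,male,140,23,25,28,32,37,42,46
lvsv,male,140,42,45,51,57,64,70,74
lvedv,male,150,82,87,95,105,115,126,133
lvesv,male,150,27,29,33,39,45,51,55
lvsv,male,150,49,52,59,66,74,81,86
lvedv,male,160,95,101,111,123,137,149,157
lvesv,male,160,32,35,40,47,54,62,67
lvsv,male,160,57,61,68,76,85,94,99
lvedv,male,170,110,118,130,146,162,177,186
lvesv,male,170,38,42,48,56,66,75,81
lvsv,male,170,66,70,78,88,98,108,114
lvedv,male,180,127,136,153,172,191,209,220
lvesv,male,180,44,49,58,68,79,90,98
lvsv,male,180,76,82,91,102,114,125,132
lvedv,male,190,145,158,179,203,226,247,260
lvesv,male,190,52,58,69,82,96,110,118
lvsv,male,190,88,95,105,118,132,145,153
lvedv,male,200,164,181,209,239,267,292,306
lvesv,male,200,60,68,83,99,116,132,142
lvsv,male,200,102,109,122,136,152,167,176
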