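parameter_id,sex,age_lo,age_hi,ethnicity,field_strength,technique,group,n,mean,sd,lower,upper,precision,method,distribution
lvedv,male,18,,,,,,6213,147,33,83,211,0,pooled_frequentist,normal
lvedv,female,18,,,,,,7269,118,24,72,164,0,pooled_frequentist,normal
lvedv_bsa,male,18,,,,,,6485,75,15,46,104,0,pooled_frequentist,normal
lvedv_bsa,female,18,,,,,,7538,69,11,46,91,0,pooled_frequentist,normal
lvesv,male,18,,,,,,6206,51,16,20,82,0,pooled_frequentist,normal
lvesv,female,18,,,,,,7264,39,11,17,60,0,pooled_frequentist,normal
lvesv_bsa,male,18,,,,,,6471,26,8,11,41,0,pooled_frequentist,normal
lvesv_bsa,female,18,,,,,,7538,23,6,11,34,0,pooled_frequentist,normal
lvsv,male,18,,,,,,6158,98,23,53,142,0,pooled_frequentist,normal
lvsv,female,18,,,,,,7214,79,16,47,111,0,pooled_frequentist,normal
lvsv_bsa,male,18,,,,,,6312,50,10,30,69,0,pooled_frequentist,normal
lvsv_bsa,female,18,,,,,,7372,47,8,31,63,0,pooled_frequentist,normal
lvef,male,18,,,,,,6472,66,7,53,79,0,pooled_frequentist,normal
lvef,female,18,,,,,,7541,67,6,55,80,0,pooled_frequentist,normal
lvm,male,18,,,,,,6205,124,23,78,169,0,pooled_frequentist,normal
lvm,female,18,,,,,,7261,87,18,52,123,0,pooled_frequentist,normal
lvm_bsa,male,18,,,,,,6374,64,10,44,84,0,pooled_frequentist,normal
lvm_bsa,female,18,,,,,,7463,52,9,35,69,0,pooled_frequentist,normal
lvco,male,18,,,,,,4719,5.5,1.4,2.6,8.3,1,pooled_frequentist,normal
lvco,female,18,,,,,,4794,4.7,1.1,2.6,6.9,1,pooled_frequentist,normal
lvci,male,18,,,,,,100,3.2,0.8,1.6,4.8,1,pooled_frequentist,normal
lvci,female,18,,,,,,100,3.0,,2.6,3.6,1,pooled_frequentist,median_iqr
lvm_lvedv,male,18,,,,,,1310,0.8,0.2,0.5,1.1,1,pooled_frequentist,normal
lvm_lvedv,female,18,,,,,,2305,0.7,0.1,0.4,1.0,1,pooled_frequentist,normal
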