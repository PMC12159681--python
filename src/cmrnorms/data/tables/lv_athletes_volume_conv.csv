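parameter_id,sex,age_lo,age_hi,ethnicity,field_strength,technique,group,n,mean,sd,lower,upper,precision,method,distribution
lvedv,male,18,,,,,regular,83,250,32,186,314,0,single_study_mean_2sd,normal
lvedv,female,18,,,,,regular,60,194,27,140,248,0,single_study_mean_2sd,normal
lvedv,male,18,,,,,elite,46,261,39,183,339,0,single_study_mean_2sd,normal
lvedv,female,18,,,,,elite,33,199,31,137,261,0,single_study_mean_2sd,normal
lvedv_bsa,male,18,,,,,regular,83,123,13,97,149,0,single_study_mean_2sd,normal
lvedv_bsa,female,18,,,,,regular,60,107,14,79,135,0,single_study_mean_2sd,normal
lvedv_bsa,male,18,,,,,elite,46,129,17,95,163,0,single_study_mean_2sd,normal
lvedv_bsa,female,18,,,,,elite,33,107,14,79,135,0,single_study_mean_2sd,normal
lvesv,male,18,,,,,regular,83,108,20,68,148,0,single_study_mean_2sd,normal
lvesv,female,18,,,,,regular,60,86,15,56,116,0,single_study_mean_2sd,normal
lvesv,male,18,,,,,elite,46,117,24,69,165,0,single_study_mean_2sd,normal
lvesv,female,18,,,,,elite,33,85,20,45,125,0,single_study_mean_2sd,normal
lvesv_bsa,male,18,,,,,regular,83,53,9,35,71,0,single_study_mean_2sd,normal
lvesv_bsa,female,18,,,,,regular,60,48,8,32,64,0,single_study_mean_2sd,normal
lvesv_bsa,male,18,,,,,elite,46,58,11,36,80,0,single_study_mean_2sd,normal
lvesv_bsa,female,18,,,,,elite,33,46,11,24,68,0,single_study_mean_2sd,normal
lvm,male,18,,,,,regular,83,125,22,81,169,0,single_study_mean_2sd,normal
lvm,female,18,,,,,regular,60,84,17,50,118,0,single_study_mean_2sd,normal
lvm,male,18,,,,,elite,46,139,28,83,195,0,single_study_mean_2sd,normal
lvm,female,18,,,,,elite,33,92,15,62,122,0,single_study_mean_2sd,normal
lvm_bsa,male,18,,,,,regular,83,62,11,40,84,0,single_study_mean_2sd,normal
lvm_bsa,female,18,,,,,regular,60,46,9,28,64,0,single_study_mean_2sd,normal
lvm_bsa,male,18,,,,,elite,46,69,13,43,95,0,single_study_mean_2sd,normal
lvm_bsa,female,18,,,,,elite,33,50,8,34,66,0,single_study_mean_2sd,normal
lvef,male,18,,,,,regular,83,57,5,47,67,0,single_study_mean_2sd,normal
lvef,female,18,,,,,regular,60,55,4,47,63,0,single_study_mean_2sd,normal
lvef,male,18,,,,,elite,46,55,5,45,65,0,single_study_mean_2sd,normal
lvef,female,18,,,,,elite,33,58,7,44,72,0,single_study_mean_2sd,normal
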