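parameter_id,sex,age_lo,age_hi,ethnicity,field_strength,technique,group,n,mean,sd,lower,upper,precision,method,distribution
lvedv_bsa,male,18,,,,,elite,101,101,12,77,125,0,single_study_mean_2sd,normal
lvedv_bsa,female,18,,,,,elite,49,89,10,69,109,0,single_study_mean_2sd,normal
lvesv_bsa,male,18,,,,,elite,101,35,7,21,49,0,single_study_mean_2sd,normal
lvesv_bsa,female,18,,,,,elite,49,30,7,16,44,0,single_study_mean_2sd,normal
lvsv_bsa,male,18,,,,,elite,101,66,8,50,82,0,single_study_mean_2sd,normal
lvsv_bsa,female,18,,,,,elite,49,59,7,45,73,0,single_study_mean_2sd,normal
lvm_bsa,male,18,,,,,elite,101,113,17,79,147,0,single_study_mean_2sd,normal
lvm_bsa,female,18,,,,,elite,49,84,12,60,108,0,single_study_mean_2sd,normal
lvef,male,18,,,,,elite,101,66,5,56,76,0,single_study_mean_2sd,normal
lvef,female,18,,,,,elite,49,66,6,54,78,0,single_study_mean_2sd,normal
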