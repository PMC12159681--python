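parameter_id,sex,age_lo,age_hi,ethnicity,field_strength,technique,group,n,mean,sd,lower,upper,precision,method,distribution
rvedv,male,18,,,,,regular,83,277,36,205,349,0,single_study_mean_2sd,normal
rvedv,female,18,,,,,regular,60,209,29,151,267,0,single_study_mean_2sd,normal
rvedv,male,18,,,,,elite,46,291,48,195,387,0,single_study_mean_2sd,normal
rvedv,female,18,,,,,elite,33,219,35,149,289,0,single_study_mean_2sd,normal
rvedv_bsa,male,18,,,,,regular,83,136,16,104,168,0,single_study_mean_2sd,normal
rvedv_bsa,female,18,,,,,regular,60,115,15,85,145,0,single_study_mean_2sd,normal
rvedv_bsa,male,18,,,,,elite,46,144,20,104,184,0,single_study_mean_2sd,normal
rvedv_bsa,female,18,,,,,elite,33,118,17,84,152,0,single_study_mean_2sd,normal
rvesv,male,18,,,,,regular,83,135,25,85,185,0,single_study_mean_2sd,normal
rvesv,female,18,,,,,regular,60,102,17,68,136,0,single_study_mean_2sd,normal
rvesv,male,18,,,,,elite,46,148,30,88,208,0,single_study_mean_2sd,normal
rvesv,female,18,,,,,elite,33,103,24,55,151,0,single_study_mean_2sd,normal
rvesv_bsa,male,18,,,,,regular,83,66,12,42,90,0,single_study_mean_2sd,normal
rvesv_bsa,female,18,,,,,regular,60,57,9,39,75,0,single_study_mean_2sd,normal
rvesv_bsa,male,18,,,,,elite,46,73,13,47,99,0,single_study_mean_2sd,normal
rvesv_bsa,female,18,,,,,elite,33,56,13,30,82,0,single_study_mean_2sd,normal
rvm,male,18,,,,,regular,83,29,6,17,41,0,single_study_mean_2sd,normal
rvm,female,18,,,,,regular,60,23,4,15,31,0,single_study_mean_2sd,normal
rvm,male,18,,,,,elite,46,30,6,18,42,0,single_study_mean_2sd,normal
rvm,female,18,,,,,elite,33,25,5,15,35,0,single_study_mean_2sd,normal
rvm_bsa,male,18,,,,,regular,83,14,3,8,20,0,single_study_mean_2sd,normal
rvm_bsa,female,18,,,,,regular,60,13,2,9,17,0,single_study_mean_2sd,normal
rvm_bsa,male,18,,,,,elite,46,15,2,11,19,0,single_study_mean_2sd,normal
rvm_bsa,female,18,,,,,elite,33,14,3,8,20,0,single_study_mean_2sd,normal
rvef,male,18,,,,,regular,83,51,4,43,59,0,single_study_mean_2sd,normal
rvef,female,18,,,,,regular,60,51,4,43,59,0,single_study_mean_2sd,normal
rvef,male,18,,,,,elite,46,50,4,42,58,0,single_study_mean_2sd,normal
rvef,female,18,,,,,elite,33,53,7,39,67,0,single_study_mean_2sd,normal
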