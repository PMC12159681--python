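parameter_id,sex,age_lo,age_hi,ethnicity,field_strength,technique,group,n,mean,sd,lower,upper,precision,method,distribution
mpa_diam_sys,male,18,,,,,,60,27.4,2.6,22,33,0,single_study_mean_2sd,normal
mpa_diam_sys,female,18,,,,,,60,25.3,2.6,20,31,0,single_study_mean_2sd,normal
mpa_diam_dia,male,18,,,,,,60,22.9,2.4,18,28,0,single_study_mean_2sd,normal
mpa_diam_dia,female,18,,,,,,60,21.2,2.1,17,25,0,single_study_mean_2sd,normal
mpa_area_sys,male,18,,,,,,60,5.9,1.1,3.7,8.1,1,single_study_mean_2sd,normal
mpa_area_sys,female,18,,,,,,60,5.0,1.0,3.0,7.0,1,single_study_mean_2sd,normal
mpa_area_dia,male,18,,,,,,60,4.2,0.8,2.6,5.8,1,single_study_mean_2sd,normal
mpa_area_dia,female,18,,,,,,60,3.6,0.7,2.2,5.0,1,single_study_mean_2sd,normal
mpa_distension,male,18,,,,,,60,42.7,17.2,8,77,0,single_study_mean_2sd,normal
mpa_distension,female,18,,,,,,60,41.8,15.7,10,73,0,single_study_mean_2sd,normal
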