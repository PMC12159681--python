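parameter_id,sex,age_lo,age_hi,ethnicity,field_strength,technique,group,n,mean,sd,lower,upper,precision,method,distribution
t1_native_myo,all,0,18,,1.5,MOLLI 3b(3s)3b(3s)5b GE,,32,1017,48,921,1113,0,single_study_mean_2sd,normal
t1_native_myo,all,0,18,,1.5,SmartT1map GE,,34,1191,62,1067,1315,0,single_study_mean_2sd,normal
t1_native_myo,all,0,18,,1.5,MOLLI 5b(3s)3b Siemens,,46,1005,40,925,1085,0,single_study_mean_2sd,normal
t1_native_myo,all,0,18,,3,MOLLI 5s(3s)3s Philips,,119,1241,35,1171,1311,0,single_study_mean_2sd,normal
t1_native_myo,all,0,18,,3,MOLLI 5s(3s)3s Siemens,,38,1223,29,1165,1281,0,single_study_mean_2sd,normal
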