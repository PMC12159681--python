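parameter_id,sex,age_lo,age_hi,ethnicity,field_strength,technique,group,n,mean,sd,lower,upper,precision,method,distribution
t2_myo,all,0,18,,3,T2 GraSE Siemens,,38,43,4.5,34,52,0,single_study_mean_2sd,normal
t2_myo,all,0,18,,3,T2 GraSE Philips,,118,44.8,2.9,39,51,0,single_study_mean_2sd,normal
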