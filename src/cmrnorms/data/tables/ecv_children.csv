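parameter_id,sex,age_lo,age_hi,ethnicity,field_strength,technique,group,n,mean,sd,lower,upper,precision,method,distribution
ecv,all,0,18,,3,MOLLI 3s(3s)5s Siemens,,15,27.0,0.6,25.8,28.2,1,single_study_mean_2sd,normal
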