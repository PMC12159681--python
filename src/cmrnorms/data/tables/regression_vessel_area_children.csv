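parameter_id,site,intercept,slope,transform,sd_residuals,units
ascending_aorta_area_pc,ascending_aorta,-0.0386,2.913,bsa,,cm^2
mpa_area_pc,main_pulmonary_artery,-0.288,3.386,bsa,,cm^2
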