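parameter_id,site,intercept,slope,transform,sd_residuals,units
aortic_diameter,aortic_sinus,0.57,19.37,sqrt_bsa,2.38,mm
aortic_diameter,sinotubular_junction,-0.03,16.91,sqrt_bsa,1.92,mm
aortic_diameter,ascending_aorta,-1.33,18.6,sqrt_bsa,1.99,mm
aortic_diameter,proximal_to_brachiocephalic,-3.38,20.07,sqrt_bsa,1.69,mm
aortic_diameter,first_transverse_segment,-3.52,18.66,sqrt_bsa,1.63,mm
aortic_diameter,second_transverse_segment,-2.63,16.5,sqrt_bsa,1.31,mm
aortic_diameter,isthmic_region,-3.37,16.52,sqrt_bsa,1.46,mm
aortic_diameter,descending_aorta,-1.12,14.42,sqrt_bsa,1.64,mm
aortic_diameter,thoracoabdominal_aorta,1.27,9.89,sqrt_bsa,1.34,mm
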