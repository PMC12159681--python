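parameter_id,site,intercept,slope,transform,sd_residuals,units
pa_diameter,mpa_axial,4.85,13.43,sqrt_bsa,2.72,mm
pa_diameter,mpa_sagittal,1.04,17.07,sqrt_bsa,2.01,mm
pa_diameter,proximal_rpa_axial,2.63,9.19,sqrt_bsa,1.65,mm
pa_diameter,distal_rpa_axial,3.9,6.25,sqrt_bsa,1.49,mm
pa_diameter,proximal_rpa_rao,-0.69,14.3,sqrt_bsa,1.76,mm
pa_diameter,distal_rpa_rao,-1.08,14.62,sqrt_bsa,1.6,mm
pa_diameter,proximal_lpa_axial,1.7,11.27,sqrt_bsa,1.37,mm
pa_diameter,distal_lpa_axial,-0.1,11.89,sqrt_bsa,1.51,mm
pa_diameter,proximal_lpa_lao,-2.13,16.82,sqrt_bsa,1.88,mm
pa_diameter,distal_lpa_lao,-2.08,13.64,sqrt_bsa,1.5,mm
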