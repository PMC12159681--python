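id,name,units,indexing,convention,plane
lvedv,LV end-diastolic volume,mL,absolute,papillary_in_mass,SAX
lvedv_bsa,LV end-diastolic volume / BSA,mL/m^2,per_bsa,papillary_in_mass,SAX
lvesv,LV end-systolic volume,mL,absolute,papillary_in_mass,SAX
lvesv_bsa,LV end-systolic volume / BSA,mL/m^2,per_bsa,papillary_in_mass,SAX
lvsv,LV stroke volume,mL,absolute,papillary_in_mass,SAX
lvsv_bsa,LV stroke volume / BSA,mL/m^2,per_bsa,papillary_in_mass,SAX
lvef,LV ejection fraction,%,absolute,papillary_in_mass,SAX
lvm,LV mass,g,absolute,papillary_in_mass,SAX
lvm_bsa,LV mass / BSA,g/m^2,per_bsa,papillary_in_mass,SAX
lvco,LV cardiac output,L/min,absolute,papillary_in_mass,SAX
lvci,LV cardiac index,L/min/m^2,per_bsa,papillary_in_mass,SAX
lvm_lvedv,LV mass to volume ratio,g/mL,absolute,papillary_in_mass,SAX
rvedv,RV end-diastolic volume,mL,absolute,papillary_in_volume,SAX
rvedv_bsa,RV end-diastolic volume / BSA,mL/m^2,per_bsa,papillary_in_volume,SAX
rvesv,RV end-systolic volume,mL,absolute,papillary_in_volume,SAX
rvesv_bsa,RV end-systolic volume / BSA,mL/m^2,per_bsa,papillary_in_volume,SAX
rvm,RV mass,g,absolute,papillary_in_volume,SAX
rvm_bsa,RV mass / BSA,g/m^2,per_bsa,papillary_in_volume,SAX
rvef,RV ejection fraction,%,absolute,papillary_in_volume,SAX
la_max_vol_bsa,Maximal LA volume / BSA,mL/m^2,per_bsa,not_applicable,axial stack
la_max_vol,Maximal LA volume (biplane area-length),mL,absolute,not_applicable,2ch+4ch
ra_max_vol_bsa,Maximal RA volume / BSA,mL/m^2,per_bsa,not_applicable,axial stack
ra_max_vol,Maximal RA volume (monoplane area-length),mL,absolute,not_applicable,4ch
t1_native_myo,Native myocardial T1 time,ms,absolute,not_applicable,mid SAX septum
ecv,Extracellular volume fraction,%,absolute,not_applicable,SAX
t2_myo,Myocardial T2 time,ms,absolute,not_applicable,mid SAX septum
mpa_diam_sys,Main pulmonary artery systolic diameter,mm,absolute,not_applicable,cross-section
mpa_diam_dia,Main pulmonary artery diastolic diameter,mm,absolute,not_applicable,cross-section
mpa_area_sys,Main pulmonary artery systolic area,cm^2,absolute,not_applicable,cross-section
mpa_area_dia,Main pulmonary artery diastolic area,cm^2,absolute,not_applicable,cross-section
mpa_distension,Main pulmonary artery distension,%,absolute,not_applicable,cross-section
aortic_area,Aortic cross-sectional area,mm^2,absolute,not_applicable,cross-section
aortic_diameter,Aortic diameter,mm,absolute,not_applicable,MR angiography
aa_distensibility,Ascending aorta distensibility,10^-3 mmHg^-1,absolute,not_applicable,cross-section
aortic_pwv,Aortic arch pulse wave velocity,m/s,absolute,not_applicable,phase contrast
pa_diameter,Pulmonary artery diameter,mm,absolute,not_applicable,MR angiography
ascending_aorta_area_pc,Ascending aorta area (phase contrast),cm^2,absolute,not_applicable,phase contrast
mpa_area_pc,Main pulmonary artery area (phase contrast),cm^2,absolute,not_applicable,phase contrast
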