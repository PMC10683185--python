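species,dipole_debye,energy_kcal,binding_printed_kcal,consistent
BNNT,13.72,-4957999.32,,1
SSZ_enol,5.24,-1058804.12,,1
SSZ_keto,7.91,-1058794.61,,1
enol_carbonyl_ver1,13.52,-6016807.22,-3.78,1
enol_carbonyl_ver2,7.71,-6016802.45,-2.27,0
enol_sulfonamide,14.96,-6016802.45,0.99,1
keto_carbonyl_ver1,21.78,-6016812.11,-18.18,1
keto_carbonyl_ver2,22.68,-6016818.58,-24.64,1
keto_sulfonamide,21.27,-6016810.92,-16.99,1
keto_pyridine,14.49,-6016799.32,-5.39,1
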