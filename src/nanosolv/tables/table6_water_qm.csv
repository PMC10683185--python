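species,dipole_debye,energy_hartree,energy_kcal,binding_printed_kcal,consistent
BNNT,13.84,-7901.11,-4958028.55,,1
SSZ_keto,13.23,-1687.24,-1058760.03,,1
keto_carbonyl_ver1,25.21,-9588.45,-6016848.33,-59.75,1
keto_carbonyl_ver2,30.21,-9588.45,-6016847.54,-58.96,1
keto_sulfonamide,26.59,-9588.47,-6016860.76,-72.18,1
keto_pyridine,17.54,-9588.46,-6016851.84,-63.26,1
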