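species,n_h2o,e_total,e_soln,elec_in_soln,vdw_in_soln
BNNT,3990,-255.66,-290.34,-291.47,1.12
SSZ_enol,4059,-11.36,-3.30,-3.29,-0.01
SSZ_keto,4059,-30.85,-22.92,-22.88,-0.04
enol_carbonyl_ver1,3983,-230.89,-265.95,-267.11,1.16
enol_carbonyl_ver2,3984,-231.31,-266.30,-267.46,1.15
enol_sulfonamide,3980,-227.90,-261.90,-263.23,1.33
keto_carbonyl_ver1,3958,-241.91,-275.87,-277.07,1.20
keto_carbonyl_ver2,3970,-233.42,-267.83,-269.10,1.27
keto_sulfonamide,3977,-230.27,-264.30,-265.57,1.27
keto_pyridine,3964,-214.66,-245.77,-246.683,0.908
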