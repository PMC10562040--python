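# Published benchmark: per-insert SPR prediction for the Gammex 1467 phantom
# on a rapid-kV-switching spectral scanner (virtual-monoenergetic images,
# 70-140 keV in 5 keV steps) against the single-energy 120 kVp stoichiometric
# baseline. Used to validate the package's percent-deviation reporting
# convention; the optimal pairs are scanner-specific and are context, not a
# target for the synthetic generator.
name,reference_spr,spectral_predicted_spr,spectral_deviation_pct,e1_kev,e2_kev,sect_predicted_spr,sect_deviation_pct
HE Cortical Bone,1.6970,1.6977,0.05,75,80,1.6983,0.08
50% CaCO3,1.4161,1.4160,-0.01,90,105,1.4179,0.13
30% CaCO3,1.2479,1.2481,0.01,110,120,1.2362,-0.94
HE Inner Bone,1.1493,1.1472,-0.18,90,95,1.1595,0.89
HE Blood 100,1.0947,1.0894,-0.48,110,115,1.0966,0.18
HE Blood 70,1.0672,1.0629,-0.40,95,100,1.0705,0.31
HE Liver,1.0488,1.0471,-0.17,95,100,1.0508,0.18
HE Blood 40,1.0311,1.0289,-0.21,85,90,1.0394,0.81
HE Brain,1.0232,1.0238,0.06,75,80,1.0297,0.63
HE Solid Water,1.0073,1.0085,0.13,105,115,1.0067,-0.06
HE Breast 50:50,0.9831,0.9830,-0.01,105,115,0.9714,-1.19
HE General Adipose,0.9585,0.9587,0.02,95,105,0.9429,-1.63
LN-450 lung,0.4400,0.4492,2.09,100,105,0.4541,3.20
LN-300 lung,0.2800,0.2799,-0.04,105,115,0.2736,-2.29
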