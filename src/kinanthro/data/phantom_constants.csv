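variable,p,s,d,tissue,kind
sum6_skinfolds,116.41,34.79,1,adipose,indicator
arm_relaxed_corrected,22.05,1.91,1,muscle,indicator
forearm_girth,25.13,1.41,1,muscle,indicator
chest_corrected,82.46,4.86,1,muscle,indicator
thigh_corrected,47.34,3.59,1,muscle,indicator
calf_corrected,30.22,1.97,1,muscle,indicator
biacromial,38.04,1.92,1,skeletal,indicator
biiliocristal,28.84,1.75,1,skeletal,indicator
humerus,6.48,0.35,1,skeletal,indicator
femur,9.52,0.48,1,skeletal,indicator
head_girth,56.00,1.44,1,skeletal,indicator
transverse_chest,27.92,1.74,1,residual,indicator
ap_chest_depth,17.50,1.38,1,residual,indicator
waist_girth,71.91,4.45,1,residual,indicator
adipose_mass,25.60,5.85,3,adipose,mass
muscle_mass,24.50,5.40,3,muscle,mass
skeletal_mass,7.90,1.52,3,skeletal,mass
residual_mass,6.10,1.24,3,residual,mass
skin_mass,3.6169,0.47,3,skin,mass
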