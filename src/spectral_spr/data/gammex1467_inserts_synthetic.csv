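# Synthetic stand-in for the Gammex 1467 tissue-surrogate insert library.
# The vendor manual's elemental compositions are not publicly deposited, so
# these are package-constructed surrogate compositions (epoxy-style resins;
# the three blood surrogates share one composition and differ only in
# density, as do the two LN lung foams). reference_spr is the published
# per-insert reference stopping-power ratio; reference electron density is
# derived at load time as reference_spr divided by the Bethe stopping factor
# of the composition, which makes the library self-consistent under the
# Bethe formula. Mass fractions are percentages and sum to 100.
name,group,H,C,N,O,Mg,Si,P,Cl,Ca,reference_spr
HE Cortical Bone,bone,3.41,31.41,1.84,36.50,0,0,0,0.04,26.80,1.6970
50% CaCO3,bone,4.77,41.63,1.52,32.00,0,0,0,0.08,20.00,1.4161
30% CaCO3,bone,6.68,53.48,2.12,25.61,0,0,0,0.11,12.00,1.2479
HE Inner Bone,bone,6.67,55.63,1.96,23.52,0,0,3.23,0.11,8.88,1.1493
HE Blood 100,soft,8.468746,67.145054,2.40,20.00,0,0,0,0.13,1.8562,1.0947
HE Blood 70,soft,8.468746,67.145054,2.40,20.00,0,0,0,0.13,1.8562,1.0672
HE Liver,soft,8.06,67.01,2.47,20.01,0,0,0,0.14,2.31,1.0488
HE Blood 40,soft,8.468746,67.145054,2.40,20.00,0,0,0,0.13,1.8562,1.0311
HE Brain,soft,10.83,72.54,1.69,14.86,0,0,0,0.08,0,1.0232
HE Solid Water,soft,8.00,67.29,2.39,19.87,0,0,0,0.14,2.31,1.0073
HE Breast 50:50,soft,8.59,70.10,2.33,17.90,0,0,0,0.13,0.95,0.9831
HE General Adipose,soft,9.06,72.29,2.25,16.27,0,0,0,0.13,0,0.9585
LN-450 lung,lung,5.727453,48.514896,1.347636,11.791815,31.9182,0.60,0,0.10,0,0.4400
LN-300 lung,lung,5.727453,48.514896,1.347636,11.791815,31.9182,0.60,0,0.10,0,0.2800
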