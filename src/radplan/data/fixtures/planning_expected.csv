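antibody_dose_mg_per_m2,limiting_organ,max_activity_mbq
0.48,spleen,1667
4.8,spleen,2886
48,red_marrow,3390
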