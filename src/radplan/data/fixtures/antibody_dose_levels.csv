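monkey_mg_per_kg,bsa_mg_per_m2,mouse_ug_per_animal
0.04,0.48,4
0.4,4.8,40
4,48,400
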