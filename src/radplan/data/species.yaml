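# FDA-style interspecies body-surface-area scaling constants.
# mg/kg x km = mg/m2. The 60 kg / km=37 human pair is used for antibody
# mg/kg conversion; the 1.89 m2 reference adult male BSA (73.7 kg,
# 175 cm) is used for whole-body activity extrapolation.
km:
  mouse: 3
  cynomolgus: 12
  human: 37
reference_weight_kg:
  mouse: 0.025
  human: 60
human_bsa_m2: 1.89
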