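# Reference adult male phantom organ masses (g).
# Values follow the widely used Cristy-Eckerman adult male tables as
# adopted by standard internal-dosimetry software; edit to taste.
name: adult_male
total_body_mass_g: 73700
organ_masses_g:
  heart_wall: 316
  liver: 1910
  lungs: 1000
  spleen: 183
  red_marrow: 1120
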