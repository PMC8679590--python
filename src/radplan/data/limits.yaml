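# Organ absorbed-dose ceilings (mGy) for maximum-activity planning.
red_marrow_mgy: 3000
other_organ_mgy: 20000
overrides: {}
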