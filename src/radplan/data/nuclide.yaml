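# 90Y: pure beta emitter. Half-life as used throughout the planning
# chain (64 h); mean beta energy per decay from standard decay data.
name: Y-90
half_life_h: 64
mean_energy_mev: 0.9337
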