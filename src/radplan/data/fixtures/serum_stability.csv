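agent,time_h,intact_pct_mean,intact_pct_sd
Y90-conjugate,0,100.0,0.0
Y90-conjugate,3,96.9,0.2
Y90-conjugate,24,94.7,0.3
Y90-conjugate,48,94.3,0.4
Y90-conjugate,96,93.7,0.7
In111-conjugate,0,100.0,0.0
In111-conjugate,3,99.8,0.2
In111-conjugate,24,99.3,1.5
In111-conjugate,48,99.3,0.2
In111-conjugate,96,98.1,1.5
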