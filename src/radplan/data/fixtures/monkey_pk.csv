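antibody_dose_mg_per_kg,cmax_pid_per_ml,auc_pid_h_per_ml,t_half_h,cl_ml_per_h_per_kg,vss_ml_per_kg
0.04,0.52,38.75,147.73,0.88,146.93
0.4,0.45,43.26,147.10,0.68,124.61
4,0.47,69.32,241.91,0.44,136.14
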