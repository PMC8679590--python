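agent,cmax_pid_per_g,auc_pid_h_per_g,t_half_h,cl_g_per_h,vss_g
Y90-conjugate,35.32,5971.67,273.38,0.02,6.25
In111-conjugate,35.94,5733.08,231.14,0.02,5.52
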