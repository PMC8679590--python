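antibody_dose_mg_per_m2,organ,mgy_per_mbq
0.48,heart_wall,2.31
0.48,liver,2.56
0.48,lungs,1.21
0.48,red_marrow,0.661
0.48,osteogenic_cells,0.680
0.48,spleen,12.0
0.48,total_body,0.382
4.8,heart_wall,2.54
4.8,liver,2.47
4.8,lungs,1.19
4.8,red_marrow,0.786
4.8,osteogenic_cells,0.817
4.8,spleen,6.93
4.8,total_body,0.423
48,heart_wall,3.28
48,liver,2.55
48,lungs,1.82
48,red_marrow,0.885
48,osteogenic_cells,0.912
48,spleen,2.77
48,total_body,0.459
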