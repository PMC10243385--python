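label,drug_pct,plga_pct,pva_pct,ow_ratio,speed_rpm,time_s,dilution_ratio,size_um,uniformity,ee_pct,dl_pct
F1,1.0,20.0,1.0,0.25,2400,60,2.2,21.3,0.3,100.2,1.0
F2,1.0,15.0,1.0,0.10,3000,90,2.0,21.4,0.3,106.8,1.1
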