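label,drug_pct,plga_pct,pva_pct,ow_ratio,speed_rpm,time_s,dilution_ratio,size_um,uniformity,ee_pct,dl_pct
M01,1,10,2.00,0.10,1000,60,6,369.72,0.58,59.00,0.56
M02,2,20,0.50,0.40,3000,120,2,26.52,0.33,91.05,1.98
M03,0,15,1.25,0.25,2000,90,10,21.25,0.26,–,–
M04,1,10,0.50,0.25,1000,120,6,193.38,0.63,89.06,1.29
M05,0,15,1.25,0.40,3000,90,2,22.33,0.39,–,–
M06,2,20,2.00,0.10,2000,60,10,45.53,0.27,104.83,2.08
M07,1,15,1.25,0.40,2000,60,6,20.69,0.25,100.41,1.10
M08,0,10,2.00,0.25,1000,90,10,431.93,0.57,–,–
M09,2,20,0.50,0.10,3000,120,2,33.00,0.25,95.94,2.25
M10,1,15,0.50,0.40,3000,120,6,26.22,0.97,46.95,0.47
M11,0,10,1.25,0.10,1000,90,10,173.77,0.45,–,–
M12,2,20,2.00,0.25,2000,60,2,24.72,0.26,101.22,1.90
M13,2,10,1.25,0.40,2000,120,2,33.31,0.50,78.47,1.35
M14,1,20,0.50,0.25,1000,90,6,827.60,0.28,95.28,0.85
M15,0,15,2.00,0.10,3000,60,10,22.60,0.73,–,–
M16,1,20,0.50,0.25,3000,60,2,19.38,0.27,102.35,0.97
M17,0,15,2.00,0.10,1000,120,10,212.03,0.38,–,–
M18,2,10,1.25,0.40,2000,90,6,17.22,0.21,87.91,1.77
M19,1,10,0.50,0.40,3000,60,10,26.47,0.40,101.61,1.05
M20,0,20,1.25,0.25,2000,120,6,23.68,0.21,–,–
M21,2,15,2.00,0.10,1000,90,2,210.69,1.05,105.70,2.06
M22,1,10,2.00,0.40,1000,60,10,185.09,1.19,96.85,1.01
M23,0,15,0.50,0.10,3000,90,6,23.61,0.22,–,–
M24,2,20,1.25,0.25,2000,120,2,23.89,0.26,98.26,2.02
# M10 ee_pct: 46.95 is the authoritative tabulated value; a narrative figure of 47.82 also circulates and is deliberately not used.
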