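response,compound,r2,r2_adj,se_y,f_stat,p_value,n_obs
DT50,DOX,0.77,0.64,0.22,5.89,,17
DT50,FLUM,0.30,0.27,0.26,8.28,,23
DT50,LINCO,0.42,0.32,0.31,4.11,,23
DT50,OTC,0.42,0.33,0.34,5.00,,18
DT50,SDZ,0.56,0.49,0.27,8.18,,25
DT50,SDX,0.49,0.41,0.27,5.80,,24
DT50,TMP,0.29,0.25,0.28,7.66,,23
DT50,TYL,0.47,0.41,0.33,7.83,,23
Kd,LINCO,0.64,0.62,0.45,40.14,<0.001,27
Kd,OTC,0.85,0.78,0.17,13.32,<0.001,20
Kd,SDZ,0.87,0.85,0.24,36.65,<0.001,22
Kd,SDX,0.87,0.83,0.27,24.66,<0.001,22
Kd,TYL,0.69,0.62,0.32,10.95,<0.001,27
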