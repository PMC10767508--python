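response,compound,term,estimate,stars
DT50,DOX,intercept,3.71,***
DT50,DOX,log_cec,-2.14,*
DT50,DOX,log_fe_ox,-0.51,*
DT50,DOX,log_clay,0.47,ns
DT50,DOX,log_som,1.70,**
DT50,DOX,ph,0.26,*
DT50,FLUM,intercept,2.22,***
DT50,FLUM,log_clay,-0.29,**
DT50,LINCO,intercept,3.11,***
DT50,LINCO,log_fe_ox,-0.51,**
DT50,LINCO,log_clay,0.55,**
DT50,LINCO,ph,-0.17,*
DT50,OTC,intercept,2.60,***
DT50,OTC,log_cec,-0.70,*
DT50,OTC,log_som,0.37,ns
DT50,SDZ,intercept,2.21,***
DT50,SDZ,depth,-0.43,**
DT50,SDZ,log_som,-0.21,*
DT50,SDZ,ph,-0.18,**
DT50,SDX,intercept,2.33,***
DT50,SDX,depth,-0.27,ns
DT50,SDX,log_som,-0.19,ns
DT50,SDX,ph,-0.16,*
DT50,TMP,intercept,2.25,***
DT50,TMP,log_som,-0.27,*
DT50,TYL,intercept,0.21,ns
DT50,TYL,log_clay,0.25,ns
DT50,TYL,ph,0.23,**
Kd,LINCO,intercept,-0.46,*
Kd,LINCO,log_clay,1.01,***
Kd,OTC,intercept,-0.61,ns
Kd,OTC,depth,-0.47,*
Kd,OTC,log_cec,0.67,*
Kd,OTC,log_al_ox,0.71,***
Kd,OTC,log_clay,-0.86,**
Kd,OTC,ph,0.19,**
Kd,SDZ,intercept,0.38,ns
Kd,SDZ,log_clay,0.50,**
Kd,SDZ,log_som,0.50,***
Kd,SDZ,ph,-0.18,**
Kd,SDX,intercept,0.77,ns
Kd,SDX,log_cec,0.30,ns
Kd,SDX,log_al_ox,0.38,ns
Kd,SDX,log_clay,0.39,*
Kd,SDX,ph,-0.33,***
Kd,TYL,intercept,0.62,ns
Kd,TYL,log_cec,-0.57,**
Kd,TYL,log_fe_ox,0.28,*
Kd,TYL,log_clay,0.82,***
Kd,TYL,ph,0.16,*
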