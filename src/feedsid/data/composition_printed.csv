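component,mean,cv_pct
DM,91.62,1.94
GE,19.25,3.8
CP,39.15,7.07
EE,8.11,32.79
Ash,6.77,7.65
CF,9.34,10.01
NDF,30.19,29.94
ADF,17.68,18.19
Ca,0.58,5.92
TP,1.16,9.67
TGS,22.35,15.19
Arg,2.36,13.18
His,1.56,10.79
Ile,1.87,22.13
Leu,2.29,5.35
Lys,1.80,21.13
Met,0.85,20.30
Phe,1.43,20.55
Thr,1.61,12.14
Trp,0.31,13.41
Val,2.29,13.72
Ala,1.65,12.57
Asp,2.50,11.73
Cys,1.16,16.67
Glu,6.36,13.44
Gly,1.71,12.06
Pro,2.65,30.92
Ser,1.72,17.15
Tyr,1.33,20.00
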