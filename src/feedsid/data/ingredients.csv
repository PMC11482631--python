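sample_id,color,heat_mid_c,heat_halfrange_c,heat_min,origin,dm,ge_mj_kg,cp,ee,ash,cf,ndf,adf,ca,tp,tgs_umol_g,arg,his,ile,leu,lys,met,phe,thr,trp,val,ala,asp,cys,glu,gly,pro,ser,tyr
RSC1,brown,130,10,30,"Liupanshui, Guizhou",93.02,19.08,43.61,7.96,7.07,8.26,30.87,15.83,0.58,1.25,21.84,2.86,1.78,2.63,2.29,2.20,0.90,1.96,1.97,0.36,2.68,2.12,3.17,1.14,8.55,2.25,2.28,2.23,1.84
RSC2,reddish brown,165,15,25,"Neijiang, Sichuan",87.95,19.07,38.66,5.81,6.62,10.25,44.25,22.25,0.58,1.08,22.81,2.03,1.52,1.54,2.29,1.22,0.73,1.61,1.65,0.30,2.25,1.64,2.39,1.05,5.83,1.65,1.83,1.55,1.29
RSC3,yellowish green,115,10,30,"Huainan, Anhui",90,18.6,38.48,7.98,6.11,9.34,24.19,16.89,0.5,0.92,23.82,2.54,1.65,1.58,2.39,1.91,0.77,1.69,1.64,0.25,2.34,1.66,2.67,1.11,6.70,1.71,1.87,1.63,1.43
RSC4,greener,40,20,90,"Hanzhong, Shaanxi",91.67,19.47,39.33,7.76,5.99,8.81,23.27,16.28,0.57,1.19,20.27,2.55,1.59,2.14,2.40,2.08,0.74,1.21,1.60,0.28,2.14,1.69,2.49,1.03,6.40,1.70,3.91,1.60,1.30
RSC5,yellowish green,95,10,25,"Xuchang, Henan",92.36,18.45,42.78,6.46,7.75,8.4,21.89,14.71,0.62,1.19,21.39,2.48,1.58,1.56,2.34,2.14,0.76,1.66,1.73,0.29,2.31,1.62,2.49,1.23,6.57,1.69,2.07,1.62,1.41
RSC6,yellowish green,115,10,30,"Xiantao, Hubei",91.57,20.11,35.15,11.76,6.42,9.72,26.61,15.91,0.56,1.05,22.97,2.18,1.60,2.06,2.38,2.04,0.95,1.25,1.66,0.29,2.28,1.76,2.53,1.69,6.11,1.74,3.17,1.63,1.38
RSC7,reddish brown,165,15,25,"Huaihua, Hunan",94.68,20.84,38.37,9.73,7.09,11.32,48.61,22.87,0.59,1.3,25.02,2.32,1.56,2.07,2.24,1.23,0.82,1.14,1.45,0.37,1.81,1.57,2.36,1.10,5.94,1.61,3.44,1.42,1.27
RSC8,brown,130,10,30,"Chongqing Municipality",92.06,18.94,41.73,7.54,7.02,8.55,27.77,13.13,0.57,1.27,20.25,2.45,1.60,1.99,2.24,1.42,1.29,1.16,1.58,0.36,2.84,1.60,2.47,1.14,5.92,1.63,3.71,1.61,1.35
RSC9,brown,130,10,30,"Xiangxiang, Hunan",91.08,18.72,36.67,7.92,6.78,9.29,29.3,19.59,0.62,1.17,20.86,2.45,1.63,2.02,2.33,1.73,0.71,1.10,1.59,0.27,2.32,1.60,2.48,1.13,6.22,1.67,2.24,1.63,1.33
RSC10,yellowish brown,95,10,60,"Hanchuan, Hubei",91.85,19.18,36.76,8.13,6.89,9.5,25.12,19.39,0.6,1.18,24.27,1.74,1.13,1.16,1.98,2.08,0.82,1.48,1.20,0.33,1.88,1.28,1.99,1.01,5.40,1.45,1.95,2.31,0.74
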