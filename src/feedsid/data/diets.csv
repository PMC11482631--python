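diet_id,dm_pct,cp_pct,marker_pct,arg,his,ile,leu,lys,met,phe,thr,trp,val,ala,asp,cys,glu,gly,pro,ser,tyr
RSC1,90.85,17.71,0.30,1.15,0.72,1.05,0.92,0.89,0.36,0.78,0.79,0.15,1.08,0.86,1.28,0.46,3.40,0.91,0.91,0.89,0.74
RSC2,90.20,12.94,0.30,0.80,0.60,0.61,0.90,0.48,0.29,0.63,0.65,0.12,0.89,0.65,0.94,0.41,2.30,0.65,0.72,0.61,0.51
RSC3,90.61,14.04,0.30,1.00,0.65,0.62,0.94,0.75,0.30,0.67,0.65,0.10,0.92,0.65,1.04,0.43,2.64,0.68,0.74,0.64,0.56
RSC4,90.36,14.19,0.30,0.99,0.62,0.83,0.93,0.81,0.29,0.47,0.63,0.11,0.83,0.66,0.97,0.40,2.48,0.66,1.51,0.62,0.50
RSC5,92.34,13.88,0.30,0.97,0.62,0.61,0.92,0.84,0.30,0.65,0.68,0.11,0.90,0.63,0.97,0.48,2.59,0.67,0.82,0.63,0.55
RSC6,91.11,14.18,0.30,0.84,0.61,0.79,0.91,0.78,0.36,0.48,0.64,0.11,0.88,0.68,0.97,0.65,2.36,0.67,1.22,0.63,0.53
RSC7,92.89,12.82,0.30,0.89,0.59,0.79,0.86,0.47,0.32,0.44,0.56,0.14,0.69,0.60,0.90,0.42,2.26,0.61,1.32,0.54,0.48
RSC8,92.46,14.21,0.30,0.96,0.62,0.78,0.88,0.56,0.51,0.45,0.62,0.14,1.11,0.63,0.96,0.45,2.31,0.64,1.44,0.63,0.53
RSC9,90.89,13.52,0.30,0.96,0.64,0.78,0.91,0.67,0.28,0.43,0.62,0.10,0.90,0.62,0.96,0.44,2.41,0.65,0.87,0.63,0.52
RSC10,91.30,11.59,0.30,0.67,0.44,0.45,0.77,0.80,0.32,0.57,0.46,0.13,0.72,0.49,0.76,0.39,2.08,0.56,0.75,0.89,0.29
NFREE,90.28,1.45,0.30,,,,,,,,,,,,,0.08,,,0.51,,
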