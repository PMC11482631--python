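component,RSC1,RSC2,RSC3,RSC4,RSC5,RSC6,RSC7,RSC8,RSC9,RSC10,mean,sem,p_value
CP,70.29,52.19,62.36,63.38,66.29,66.09,46.54,54.76,60.46,54.81,59.72,1.29,<0.01
Arg,75.56,70.61,80.29,77.19,75.38,78.09,75.59,73.39,79.82,68.94,75.49,1.07,0.28
His,73.22,72.62,76.80,68.01,67.27,73.71,81.92,86.27,88.41,83.20,77.14,1.26,<0.01
Ile,81.20,71.92,72.45,80.09,76.50,84.81,78.38,78.73,81.65,66.13,77.19,0.91,<0.01
Leu,72.30,73.35,76.54,75.59,79.96,81.19,77.42,60.59,51.72,53.25,70.19,2.04,<0.01
Lys,64.34,41.12,65.21,67.90,71.61,68.56,39.94,64.70,64.12,72.23,61.97,2.16,<0.01
Met,64.76,53.52,46.08,58.70,49.67,52.17,83.92,81.18,81.99,81.05,65.31,2.39,<0.01
Phe,76.87,74.26,76.44,67.30,76.58,75.29,83.22,88.51,88.89,85.34,79.27,1.08,<0.01
Thr,68.20,64.24,66.55,62.81,65.36,71.63,66.37,68.24,75.86,69.58,67.88,1.16,0.37
Trp,84.12,80.20,73.75,78.11,80.59,81.69,81.40,83.36,75.91,79.98,79.91,0.68,<0.01
Val,81.62,77.76,77.99,80.57,83.36,79.91,68.88,82.89,82.55,59.86,77.54,1.48,<0.01
Ala,73.80,68.54,70.70,69.53,73.43,74.34,64.28,68.89,75.35,67.39,70.62,0.96,0.20
Asp,73.74,67.17,71.78,69.05,72.67,73.33,66.47,67.98,73.88,66.22,70.23,0.88,0.21
Cys,67.90,66.84,71.11,64.24,76.15,60.58,80.28,83.27,82.67,69.21,72.23,1.56,<0.01
Glu,86.46,80.33,83.02,81.26,83.79,84.37,77.10,82.10,89.62,83.73,83.18,0.79,<0.05
Gly,74.65,63.50,66.55,62.44,60.50,62.30,32.28,35.01,56.10,57.49,57.08,2.17,<0.01
Pro,55.06,47.90,52.08,63.70,24.90,50.26,44.90,63.77,61.72,46.77,51.11,2.83,0.33
Ser,78.99,69.58,75.54,71.68,75.14,69.31,65.26,74.37,80.84,84.47,74.52,1.16,<0.01
Tyr,79.09,73.49,75.87,75.02,78.86,79.40,74.98,70.97,76.49,67.82,75.20,0.92,0.09
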