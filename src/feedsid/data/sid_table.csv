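component,RSC1,RSC2,RSC3,RSC4,RSC5,RSC6,RSC7,RSC8,RSC9,RSC10,mean,sem,p_value
CP,81.19,67.00,76.07,76.9,80.42,79.73,61.92,68.59,74.74,71.54,73.81,1.18,<0.001
Arg,91.04,92.55,98.09,95.04,93.9,99.27,96.06,92.23,98.4,95.48,95.21,1.02,0.72
His,76.17,76.14,80.05,71.42,70.73,77.16,85.56,89.71,91.73,88.07,80.68,1.27,<0.01
Ile,86.05,80.22,80.72,86.21,85.04,91.28,85,85.44,88.19,77.55,84.57,0.77,<0.01
Leu,76.53,77.65,80.67,79.75,84.27,85.48,82.06,65.11,56.01,58.35,74.59,2.02,<0.01
Lys,65.13,42.56,66.14,68.75,72.45,69.46,41.45,65.98,65.16,73.11,63.02,2.14,<0.01
Met,68.50,58.17,50.56,63.35,54.25,55.89,88.28,83.89,86.86,85.35,69.51,2.37,<0.01
Phe,82.48,81.12,82.99,76.56,83.4,84.35,93.44,98.38,99.03,93.04,87.48,1.17,<0.01
Thr,77.48,75.38,77.77,74.42,76.23,83.11,79.75,80.25,87.66,85.42,79.75,1.19,0.17
Trp,96.07,94.77,91.41,93.7,96.26,97.76,93.97,96.05,92.48,93.84,94.63,0.60,0.43
Val,86.98,84.24,84.28,87.48,89.87,86.50,77.49,88.21,88.97,67.88,84.19,1.42,<0.01
Ala,84.45,82.60,84.78,83.38,88.14,87.94,79.83,83.77,90.09,86.10,85.11,0.94,0.40
Asp,79.25,74.56,78.49,76.27,80.00,80.57,74.43,75.40,81.17,75.46,77.56,0.85,0.47
Cys,76.69,76.51,80.32,74.20,79.87,66.76,90.02,92.42,91.76,79.52,80.80,1.58,<0.01
Glu,89.23,84.38,86.56,85.03,87.48,88.36,81.35,86.24,93.52,88.26,87.04,0.78,<0.05
Gly,84.86,77.54,80.22,76.36,74.57,76.12,47.70,49.84,70.30,74.11,71.16,2.09,<0.01
Pro,118.68,127.87,130.46,101.85,95.63,97.43,88.76,103.74,128.22,123.64,111.63,3.38,<0.01
Ser,85.58,79.05,84.68,81.01,84.5,78.68,76.25,83.83,90.07,91.06,83.47,1.08,0.021
Tyr,86.76,84.49,86.09,86.26,89.38,90.12,87.13,81.96,87.51,87.92,86.76,0.84,0.70
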