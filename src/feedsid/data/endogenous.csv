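component,g_kg_dmi
CP,21.24
Arg,1.96
His,0.23
Ile,0.56
Leu,0.43
Lys,0.08
Met,0.15
Phe,0.48
Thr,0.8
Trp,0.19
Val,0.6
Ala,1.01
Asp,0.77
Cys,0.04
Glu,1.03
Gly,1.02
Pro,6.39
Ser,0.64
Tyr,0.63
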