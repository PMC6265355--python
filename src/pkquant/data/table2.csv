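method,outcome,mean,sd,icc,absvar_pct,sem,md_pct
Cerebellum,V_T,0.67,0.16,0.81,13,0.07,29
Cerebellum,V_S,0.43,0.11,0.67,18,0.06,39
Cerebellum,BP_ND,1.91,0.31,-0.31,21,0.36,52
SVCA4 reference TAC,V_T,0.74,0.18,0.67,18,0.1,38
SVCA4 reference TAC,V_S,0.46,0.13,0.69,20,0.07,43
SVCA4 reference TAC,BP_ND,1.72,0.52,0.77,22,0.25,40
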