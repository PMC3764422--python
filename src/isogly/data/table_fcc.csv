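reaction,model0,model18
HXT,0.844,1.467
HXK,0.201,1.995
ATPase,-0.076,-3.303
PFK,0.045,0.356
Glycerol_branch,-0.017,
Glycogen_branch,-0.009,
Succinate_branch,-0.008,
TDH,0.007,0.118
ADH,0.006,0.359
Trehalose_branch,-0.006,
FBA,0.005,0.102
PGI,0.005,0.023
ENO,0.003,0.016
PGK,0.000,0.172
PYK,0.000,0.063
GPM,0.000,-0.044
PDC,0.000,0.001
TPI,0.000,0.008
AK,0.000,0.000
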