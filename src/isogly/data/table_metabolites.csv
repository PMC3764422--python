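id,name,chebi,copies_per_cell_thousands,sem_percent,observed_mM,predicted_mM,prior_mM
DHAP,Dihydroxyacetone phosphate,16108,3500,18.9,1.162,1.584,1.004
F16bP,Fructose 1-6-bisphosphate,28013,13800,20.2,4.583,2.780,6.221
F6P,Fructose 6-phosphate,16084,709,14.8,0.235,0.325,0.625
G3P,Glycerol 3-phosphate,15978,825,24.3,0.274,0.226,0.150
G6P,Glucose 6-phosphate,17665,2330,9.7,0.774,1.213,2.675
GAP,Glyceraldehyde 3-phosphate,29052,951,26.9,0.316,0.067,0.045
GLC,Glucose,4167,18900,4.6,6.277,0.635,0.098
PEP,Phosphoenolpyruvate,18021,1840,23.5,0.611,0.477,0.063
PYR,Pyruvate,15361,6350,16.6,2.109,3.329,1.815
P2G+P3G,2- plus 3-phosphoglycerate,17835;17794,1620,17.7,0.538,0.613,1.013
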