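reaction,isoenzyme,parameter,value,sem_percent,prior_value,unit
ADH,Adh1p,kcat,176,1.3,,1/s
ADH,Adh1p,Kacald,0.462,5.3,1.11,mM
ADH,Adh5p,kcat,0,0,,1/s
ENO,Eno1p,kcat,7.6,1.9,,1/s
ENO,Eno1p,Kp2g,0.043,10,0.04,mM
ENO,Eno2p,kcat,19.9,,,1/s
ENO,Eno2p,Kp2g,0.104,,0.04,mM
FBA,Fba1p,kcat,4.14,1.5,,1/s
FBA,Fba1p,Kf16bp,0.451,5.3,0.3,mM
GPM,Gpm1p,kcat,400,,,1/s
GPM,Gpm1p,Kp2g,1.41,,0.08,mM
HXK,Glk1p,kcat,0.0721,,,1/s
HXK,Glk1p,Kglc,0.0106,,0.08,mM
HXK,Glk1p,Katp,0.865,,0.15,mM
HXK,Hxk1p,kcat,10.2,,,1/s
HXK,Hxk1p,Kglc,0.15,,0.08,mM
HXK,Hxk1p,Katp,0.293,,0.15,mM
HXK,Hxk2p,kcat,63.1,,,1/s
HXK,Hxk2p,Kglc,0.2,,0.08,mM
HXK,Hxk2p,Katp,0.195,,0.15,mM
PDC,Pdc1p,kcat,12.1,3.5,,1/s
PDC,Pdc1p,Kpyr,8.5,10,4.33,mM
PDC,Pdc5p,kcat,10.3,2.1,,1/s
PDC,Pdc5p,Kpyr,7.08,5.7,4.33,mM
PDC,Pdc6p,kcat,9.21,,,1/s
PDC,Pdc6p,Kpyr,2.92,,4.33,mM
PFK,Pfk1p:Pfk2p,kcat,210,1.8,,1/s
PGI,Pgi1p,kcat,487,3.7,,1/s
PGI,Pgi1p,Kg6p,1.03,19,1.4,mM
PGI,Pgi1p,Kf6p,0.307,6.8,0.3,mM
PGK,Pgk1p,kcat,58.6,,,1/s
PGK,Pgk1p,Kp3g,4.58,,0.53,mM
PGK,Pgk1p,Katp,1.99,,0.3,mM
PGK,Pgk1p,nHadp,2,,,
PYK,Cdc19p,kcat,20.1,2.9,,1/s
PYK,Cdc19p,Kpep,0.281,12,0.14,mM
PYK,Cdc19p,Kadp,0.243,13,0.53,mM
PYK,Pyk2p,kcat,0,0,,1/s
TDH,Tdh1p,kcat,19.1,1.5,,1/s
TDH,Tdh1p,Kgap,0.495,7.5,0.21,mM
TDH,Tdh2p,kcat,8.63,,,1/s
TDH,Tdh2p,Kgap,0.77,,0.21,mM
TDH,Tdh3p,kcat,18.2,1.8,,1/s
TDH,Tdh3p,Kgap,0.423,9.2,0.21,mM
TDH,Tdh3p,Kbpg,0.909,,0.0098,mM
TPI,Tpi1p,kcat,564,1.5,,1/s
TPI,Tpi1p,Kdhap,6.45,5,,mM
TPI,Tpi1p,Kgap,5.25,12,,mM
TPI,Tpi1p,Kigap,35.1,3.1,,mM
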