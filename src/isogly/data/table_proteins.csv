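reaction,isoenzyme,uniprot,copies_per_cell,sem_percent
ADH,Adh1p,P00330,494000,1.1
ADH,Adh5p,P38113,12800,8.1
ENO,Eno1p,P00924,2070000,0.9
ENO,Eno2p,P00925,5950000,0.7
FBA,Fba1p,P14540,4030000,
GPM,Gpm1p,P00950,2200000,0.6
HXK,Glk1p,P17709,136000,5.5
HXK,Hxk1p,P04806,50500,1.1
HXK,Hxk2p,P04807,185000,0.6
PDC,Pdc1p,P06169,3220000,0.8
PDC,Pdc5p,P16467,37200,19.1
PDC,Pdc6p,P26263,19700,1.7
PFK,Pfk1p,P16861,141000,0.7
PFK,Pfk2p,P16862,118000,2.8
PGI,Pgi1p,P12709,416000,0.6
PGK,Pgk1p,P00560,776000,1.5
PYK,Cdc19p,P00549,6170000,1.3
PYK,Pyk2p,P52489,18300,11.4
TDH,Tdh1p,P00360,1060000,1.2
TDH,Tdh2p,P00358,0,
TDH,Tdh3p,P00359,12700000,0.9
TPI,Tpi1p,P00942,886000,0.8
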