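iteration,reaction,biomodels_id,jws_id
0,,MODEL1303260000,Smallbone0
1,HXT,MODEL1303260001,Smallbone1
2,HXK,MODEL1303260002,Smallbone2
3,ATPase,MODEL1303260003,Smallbone3
4,Glycerol_branch,MODEL1303260004,Smallbone4
5,PFK,MODEL1303260005,Smallbone5
6,Glycogen_branch,MODEL1303260006,Smallbone6
7,Succinate_branch,MODEL1303260007,Smallbone7
8,PDC,MODEL1303260008,Smallbone8
9,TDH,MODEL1303260009,Smallbone9
10,FBA,MODEL1303260010,Smallbone10
11,PGI,MODEL1303260011,Smallbone11
12,ENO,MODEL1303260012,Smallbone12
13,PGK,MODEL1303260013,Smallbone13
14,ADH,MODEL1303260014,Smallbone14
15,GPM,MODEL1303260015,Smallbone15
16,PYK,MODEL1303260016,Smallbone16
17,TPI,MODEL1303260017,Smallbone17
18,,MODEL1303260018,Smallbone18
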