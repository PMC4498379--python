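host,T7,ara,T5,tet,tac_trp
BL21(DE3),40,1,1,2,2
C43(DE3),18,10,1,0,0
C41(DE3),16,0,0,0,0
BL21(DE3)pLysS,12,2,1,0,0
BL21(DE3)CodonPlus,7,0,0,1,1
BL21Star(DE3),1,1,0,0,0
BL21(DE3)RosettapLysS,1,0,0,0,0
BL21(DE3)Tuner,1,0,0,0,1
BL21Rosetta,2,0,0,0,0
BL21(AI),0,1,0,0,0
BL21-Gold,1,0,0,0,0
BL21-T1R,0,4,0,0,0
Lemo21,1,0,0,0,0
OrigamiB,0,0,1,0,0
B834,1,0,0,1,1
BLR,0,0,0,0,1
DH10B/TOP10,0,3,0,0,0
XL1-Blue,0,1,4,0,1
DH5a,0,0,0,1,3
SG13009,0,0,2,0,0
MC4100,0,1,0,0,0
SCM6,0,1,0,0,0
MC1061,0,2,0,0,0
JM83,0,0,0,2,0
M15,0,0,1,0,0
KRX,0,0,0,0,1
JM109,0,0,0,0,1
Not specified,1,0,0,0,2
Other,0,1,0,1,0
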