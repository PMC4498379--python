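host,T7,native,ara,tac_trp,T5,tet,other
BL21(DE3),28,2,0,3,0,0,0
C43(DE3),10,0,4,0,0,0,0
C41(DE3),7,0,0,0,0,0,0
BL21(DE3)pLysS,6,0,0,0,0,0,0
BL21(DE3)pRIL,1,0,0,0,0,0,0
BL21Star(DE3),1,0,0,0,0,0,0
BL21(DE3)StarpLysS,1,0,0,0,0,0,0
BL21(DE3)Tuner,2,0,0,0,0,0,0
BL21-Gold,3,0,0,0,0,0,0
B834(DE3),3,0,1,0,0,1,0
XL1-Blue,0,2,0,1,1,0,0
DH5a,0,2,0,0,0,0,1
JM109,0,1,0,0,1,0,0
TOP10,0,1,0,1,0,0,0
BZB1007,0,2,0,0,0,0,0
HN705,0,1,0,0,0,0,0
LS6164,0,0,1,0,0,0,0
LE392,0,0,1,0,0,0,0
UT5600,0,0,0,0,0,0,1
WH1061,0,0,0,1,0,0,0
MEG119,0,1,0,0,0,0,0
LMG194,0,0,1,0,0,0,0
HN741,0,0,0,1,0,0,0
LCB2048,0,0,0,1,0,0,0
AW740,0,1,0,0,0,0,0
RK20,0,0,0,1,0,0,0
MH225,0,1,0,0,0,0,0
TNE012,0,1,0,0,0,0,0
FT004,0,1,0,0,0,0,0
DW35,0,1,0,0,0,0,0
MC4100,0,1,0,0,0,0,0
GO105,0,1,0,0,0,0,0
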