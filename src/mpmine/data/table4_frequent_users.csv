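lab,n_articles,C41(DE3):pRSET,C41(DE3):pHis/pMW7,C41(DE3):pET,C43(DE3):pET
Fersht A.R.,27,20,0,2,0
Lowe J.,20,3,15,2,0
Clarke J.,18,8,7,0,0
Bycroft M.,17,13,0,0,0
De la Cruz F.,12,0,0,6,3
Winkler H.H.,10,0,0,4,2
Dimroth P.,10,0,0,0,7
Suh S.W.,10,0,0,0,4
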