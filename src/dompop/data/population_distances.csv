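population,YMF,FHB,SDG,SEG,XV,TF,WZT,SP
YMF,,0.1762,0.1840,0.2198,0.2420,0.1883,0.2489,0.2200
FHB,0.0335,,0.1789,0.2151,0.2321,0.2118,0.2431,0.2115
SDG,0.0351,0.0372,,0.1385,0.1911,0.1024,0.1650,0.1645
SEG,0.0418,0.0429,0.0208,,0.1459,0.1641,0.2116,0.2009
XV,0.0574,0.0553,0.0321,0.0388,,0.1787,0.2581,0.2036
TF,0.0391,0.0472,0.0201,0.0248,0.0304,,0.1579,0.1478
WZT,0.0607,0.0585,0.0431,0.0282,0.0611,0.0419,,0.1943
SP,0.0429,0.0421,0.0295,0.0364,0.0325,0.0301,0.0636,
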