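fingerprint,LR,SVM,GDBT,AdaBT,XGBT,RF,ExtraTrees,LGBT,CatBT
AP2DFP,0.7222,0.6978,0.7322,0.7233,0.7222,0.7067,0.6944,0.6911,0.7278
EstateFP,0.7078,0.7044,0.7278,0.6811,0.7322,0.7433,0.7211,0.7233,0.7289
ExtendedFP,0.7789,0.7322,0.7511,0.7355,0.7556,0.7778,0.7333,0.7689,0.7933
FP,0.7133,0.6878,0.7500,0.7111,0.7478,0.7444,0.7056,0.7422,0.7811
GraphOnlyFP,0.7067,0.6689,0.7267,0.7056,0.7211,0.7345,0.7089,0.7178,0.7151
KRFP,0.7500,0.7344,0.7522,0.7211,0.7578,0.7811,0.7622,0.7611,0.7789
MaccsFP,0.7300,0.7045,0.7389,0.7256,0.7578,0.7722,0.7456,0.7589,0.7722
nAP2DFP,0.6933,0.6822,0.7144,0.6889,0.7078,0.7044,0.7055,0.7033,0.7033
nKRFP,0.7522,0.7056,0.7589,0.7356,0.7544,0.7733,0.7567,0.7545,0.7578
nSubstructreFP,0.7111,0.7033,0.7644,0.7111,0.7378,0.7700,0.7355,0.7289,0.7633
PubchemFP,0.7278,0.6956,0.7522,0.7100,0.7389,0.7500,0.7167,0.7322,0.7589
SubstructreFP,0.7300,0.7267,0.7500,0.7378,0.7244,0.7911,0.7700,0.7189,0.7622
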