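fingerprint,average_accuracy
ExtendedFP,0.7693
KRFP,0.7662
MaccsFP,0.7600
nKRFP,0.7598
FP,0.7531
nSubstructreFP,0.7529
SubstructreFP,0.7493
PubchemFP,0.7464
EstateFP,0.7311
GraphOnlyFP,0.7230
AP2DFP,0.7160
nAP2DFP,0.7067
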