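,DC,MH,JJ,HC,GD,SG,JC
DC,,0.114,0.390,0.338,0.259,0.290,0.474
MH,0.114,,0.370,0.336,0.269,0.307,0.470
JJ,0.426,0.363,,0.179,0.285,0.375,0.533
HC,0.432,0.316,0.205,,0.112,0.289,0.430
GD,0.464,0.308,0.251,0.102,,0.118,0.276
SG,0.399,0.286,0.146,0.106,0.109,,0.266
JC,0.515,0.463,0.393,0.284,0.431,0.322,
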