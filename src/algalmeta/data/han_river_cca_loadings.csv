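variable,ALL,Up,Mid,Down
temperature,-0.061,0.893,-0.547,-0.801
conductivity,0.743,0.546,0.237,0.408
pH,0.354,0.308,0.413,0.625
BOD,0.57,0.138,0.598,0.659
COD,0.711,0.655,0.214,0.361
TN,0.355,0.245,0.193,0.168
NH4,0.072,0.102,0.234,0.125
TP,0.189,0.219,-0.027,-0.095
PO4,0.012,0.481,-0.155,-0.257
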