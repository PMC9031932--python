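reference,peak,G3,G4,G5,G6,G7
G2,1,0.14,<0.01,0.02,0.13,1.58
G2,2,1.59,1.96,2.11,2.24,2.46
G2,5,0.23,0.02,0.08,1.49,3.49
G2,6,0.12,<0.01,0.11,0.7,0.72
G2,7,0.21,0.08,3.57,3.15,4.42
G2,8,0.52,0.19,8.41,7.31,10.47
G2,9,0.02,0.06,<0.01,0.08,0.05
G2,10,<0.01,<0.01,0.09,0.64,1.36
G2,11,0.02,0.04,0.52,1.33,3.03
G2,12,0.2,0.06,0.08,0.02,0.57
G2,13,0.03,0.02,0.14,0.27,0.91
G1,2,4.57,5.66,6.07,6.45,7.09
G1,3,0.05,3.46,3.08,<0.01,0.01
G1,4,3.65,3.48,0.78,0.09,0.14
G1,15,0.23,0.56,0.5,0.14,0
G1,14,0,0,NEW:1:minor,NEW:13.39:major,NEW:1.89:minor
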