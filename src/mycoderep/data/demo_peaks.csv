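peak,mz,adduct,polarity,rt,uv_maxima,isotope_mz,isotope_intensity
1,309.10,[M+H]+,positive,1.67,232,,
2,679.59,[M+H]+,positive,2.87,231,,
3,777.38,[M+H]+,positive,6.40,231,,
4,759.36,[M+H]+,positive,7.81,230;280,,
5,585.27,[M+H]+,positive,9.30,229;264;280;422,,
6,527.22,[M+H]+,positive,9.99,240;312;369;417,,
7,427.26,[M+Na]+,positive,11.80,243;275;313;364,,
8,459.31,[M+H]+,positive,12.15,246;285,,
9,507.38,[M+H]+,positive,16.26,END_ABSORPTION,,
10,1106.49,[M+Na]+,positive,17.78,272;350,,
11,1135.35,[M+Na]+,positive,18.20,273;346,,
12,606.07,[M-H]-,negative,2.16,231,,
13,362.92,[M-H]-,negative,8.87,226;264;278;420,,
14,367.19,[M-H]-,negative,11.54,244;275;313;361,367.19;369.11;371.19,1;0.666667;0.111111
15,441.07,[M-H]-,negative,13.50,237;264,441.07;443.02;444.99;446.12,1;1;0.333333;0.037037
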