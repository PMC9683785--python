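# |h3J_NC'| trans-hydrogen-bond scalar couplings (Hz) for six KOW-domain beta-barrels, from long-range HNCO measurements; H-bonds at structurally equivalent barrel positions share a group number.
group,sheet,domain,donor,acceptor,abs_J,sigma_J,missing_reason
1,b1-b2,EcNusG,131,148,0.69,0.0077,
1,b1-b2,MtNusG,188,205,0.61,0.0098,
1,b1-b2,MjSpt5,92,109,0.70,0.013,
1,b1-b2,hSpt5,707,724,0.60,0.0074,
1,b1-b2,EcRfaH,113,130,0.76,0.020,
1,b1-b2,VcRfaH,116,133,0.87,0.015,
2,b1-b2,EcNusG,148,132,0.72,0.0083,
2,b1-b2,MtNusG,205,189,0.69,0.0094,
2,b1-b2,MjSpt5,109,93,0.79,0.0088,
2,b1-b2,hSpt5,724,708,,,peak overlap
2,b1-b2,EcRfaH,130,114,0.53,0.051,
2,b1-b2,VcRfaH,133,117,0.59,0.024,
3,b1-b2,EcNusG,134,146,0.67,0.0081,
3,b1-b2,MtNusG,191,203,0.56,0.011,
3,b1-b2,MjSpt5,95,107,0.77,0.012,
3,b1-b2,hSpt5,710,722,0.70,0.0077,
3,b1-b2,EcRfaH,116,128,0.65,0.027,
3,b1-b2,VcRfaH,119,131,,,peak overlap
4,b1-b2,EcNusG,146,134,0.62,0.0096,
4,b1-b2,MtNusG,203,191,0.62,0.0094,
4,b1-b2,MjSpt5,107,95,0.67,0.0095,
4,b1-b2,hSpt5,722,710,0.50,0.019,
4,b1-b2,EcRfaH,128,116,,,peak overlap
4,b1-b2,VcRfaH,131,119,0.46,0.020,
5,b1-b2,EcNusG,136,144,0.65,0.0073,
5,b1-b2,MtNusG,193,201,0.65,0.0080,
5,b1-b2,MjSpt5,97,105,0.68,0.048,
5,b1-b2,hSpt5,712,720,,,no HNCO peak
5,b1-b2,EcRfaH,118,126,0.53,0.056,
5,b1-b2,VcRfaH,121,129,0.57,0.014,
6,b1-b2,EcNusG,143,136,0.65,0.0088,
6,b1-b2,MtNusG,200,193,0.76,0.013,
6,b1-b2,MjSpt5,104,97,0.82,0.012,
6,b1-b2,hSpt5,719,713,,,peak overlap
6,b1-b2,EcRfaH,125,118,0.66,0.026,
6,b1-b2,VcRfaH,128,121,0.62,0.017,
7,b2-b3,EcNusG,147,161,0.37,0.0105,
7,b2-b3,MtNusG,204,218,0.31,0.015,
7,b2-b3,MjSpt5,108,122,0.54,0.010,
7,b2-b3,hSpt5,723,735,,,peak too weak to quantify
7,b2-b3,EcRfaH,129,142,0.41,0.029,
7,b2-b3,VcRfaH,132,145,0.42,0.019,
8,b2-b3,EcNusG,161,147,,,peak overlap
8,b2-b3,MtNusG,218,204,0.69,0.011,
8,b2-b3,MjSpt5,122,108,0.65,0.010,
8,b2-b3,hSpt5,735,723,,,peak overlap
8,b2-b3,EcRfaH,142,129,0.70,0.019,
8,b2-b3,VcRfaH,145,132,0.69,0.027,
9,b2-b3,EcNusG,149,159,0.67,0.012,
9,b2-b3,MtNusG,206,216,0.53,0.013,
9,b2-b3,MjSpt5,110,120,0.57,0.030,
9,b2-b3,hSpt5,725,734,0.71,0.010,
9,b2-b3,EcRfaH,131,140,0.48,0.032,
9,b2-b3,VcRfaH,134,143,0.61,0.036,
10,b2-b3,EcNusG,159,150,0.50,0.0086,
10,b2-b3,MtNusG,216,207,0.45,0.012,
10,b2-b3,MjSpt5,120,111,0.60,0.010,
10,b2-b3,hSpt5,733,726,,,not determined
10,b2-b3,EcRfaH,140,132,0.96,0.021,
10,b2-b3,VcRfaH,143,135,1.0,0.011,
11,b2-b3,EcNusG,152,157,0.46,0.019,
11,b2-b3,MtNusG,209,214,,,peak overlap
11,b2-b3,MjSpt5,113,118,,,not determined
11,b2-b3,hSpt5,728,731,0.61,0.012,
11,b2-b3,EcRfaH,134,138,,,not determined
11,b2-b3,VcRfaH,137,141,,,not determined
12,b3-b4,EcNusG,158,173,0.78,0.0077,
12,b3-b4,MtNusG,215,230,0.83,0.0088,
12,b3-b4,MjSpt5,119,134,,,no HNCO peak
12,b3-b4,hSpt5,732,745,0.59,0.009,
12,b3-b4,EcRfaH,139,154,0.60,0.034,
12,b3-b4,VcRfaH,142,157,,,peak overlap
13,b3-b4,EcNusG,173,158,0.64,0.010,
13,b3-b4,MtNusG,230,215,0.62,0.011,
13,b3-b4,MjSpt5,134,119,0.62,0.010,
13,b3-b4,hSpt5,745,732,0.62,0.019,
13,b3-b4,EcRfaH,154,139,,,no HNCO peak
13,b3-b4,VcRfaH,157,142,0.68,0.015,
14,b3-b4,EcNusG,160,171,0.73,0.0056,
14,b3-b4,MtNusG,217,228,0.75,0.0089,
14,b3-b4,MjSpt5,121,132,0.88,0.012,
14,b3-b4,hSpt5,734,743,0.69,0.039,
14,b3-b4,EcRfaH,141,152,0.65,0.049,
14,b3-b4,VcRfaH,144,155,0.58,0.019,
15,b3-b4,EcNusG,171,161,,,peak overlap
15,b3-b4,MtNusG,228,217,0.73,0.0062,
15,b3-b4,MjSpt5,132,121,0.47,0.014,
15,b3-b4,hSpt5,743,734,0.49,0.029,
15,b3-b4,EcRfaH,152,141,,,not determined
15,b3-b4,VcRfaH,155,144,0.72,0.021,
16,b3-b4,EcNusG,162,169,0.51,0.0074,
16,b3-b4,MtNusG,219,226,0.50,0.0090,
16,b3-b4,MjSpt5,123,130,,,no H-bond distance
16,b3-b4,hSpt5,736,741,0.63,0.033,
16,b3-b4,EcRfaH,143,150,0.75,0.033,
16,b3-b4,VcRfaH,146,153,0.49,0.024,
17,b3-b4,EcNusG,169,162,0.60,0.0066,
17,b3-b4,MtNusG,226,219,0.61,0.0091,
17,b3-b4,MjSpt5,,,,,no equivalent
17,b3-b4,hSpt5,741,736,,,no H-bond orientation
17,b3-b4,EcRfaH,150,143,0.47,0.052,
17,b3-b4,VcRfaH,153,146,0.48,0.015,
18,b3-b4,EcNusG,167,164,,,not determined
18,b3-b4,MtNusG,224,221,0.20,0.019,
18,b3-b4,MjSpt5,,,,,no equivalent
18,b3-b4,hSpt5,,,,,no equivalent
18,b3-b4,EcRfaH,148,145,,,no H-bond orientation
18,b3-b4,VcRfaH,151,148,,,no HNCO peak
19,b5-b1,EcNusG,137,177,0.46,0.017,
19,b5-b1,MtNusG,194,234,0.52,0.025,
19,b5-b1,MjSpt5,98,138,,,no HNCO peak
19,b5-b1,hSpt5,713,749,,,no HNCO peak
19,b5-b1,EcRfaH,119,158,,,peak overlap
19,b5-b1,VcRfaH,122,161,,,not determined
20,b5-b1,EcNusG,179,135,,,peak overlap
20,b5-b1,MtNusG,236,192,0.47,0.016,
20,b5-b1,MjSpt5,140,96,,,peak overlap
20,b5-b1,hSpt5,751,711,,,not determined
20,b5-b1,EcRfaH,160,117,0.51,0.036,
20,b5-b1,VcRfaH,163,120,0.57,0.037,
21,b5-b1,EcNusG,135,179,0.73,0.0060,
21,b5-b1,MtNusG,192,236,,,peak overlap
21,b5-b1,MjSpt5,96,140,,,peak overlap
21,b5-b1,hSpt5,711,751,0.68,0.023,
21,b5-b1,EcRfaH,117,160,0.68,0.015,
21,b5-b1,VcRfaH,120,163,0.53,0.016,
22,b5-b1,EcNusG,181,133,,,not determined
22,b5-b1,MtNusG,238,190,,,not determined
22,b5-b1,MjSpt5,142,94,0.46,0.023,
22,b5-b1,hSpt5,753,709,,,not determined
22,b5-b1,EcRfaH,162,115,,,not determined
22,b5-b1,VcRfaH,165,118,,,not determined
23,b5-b1,MjSpt5,143,94,0.27,0.022,
24,b5-b1,MjSpt5,94,143,0.57,0.010,
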