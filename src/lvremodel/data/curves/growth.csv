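concentration,response
0,0.79344262295081958
0.050000000000000003,0.8501170960187352
0.10000000000000001,0.90163934426229508
0.20999999999999999,1
0.40000000000000002,1.1334894613583137
0.69999999999999996,1.2835101253616199
1,1.3885245901639343
1.3999999999999999,1.4877049180327868
2,1.5868852459016392
3,1.6860655737704917
4.5,1.7672131147540984
6.5,1.8249180327868848
9,1.864590163934426
12,1.8920554854981082
16,1.9135969141755063
20,1.9269320843091335
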