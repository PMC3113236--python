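concentration,response
0,0
0.050000000000000003,0.035328909298725807
0.10000000000000001,0.51695959545809189
0.20999999999999999,8.2601481032748403
0.40000000000000002,77.434570978211184
0.69999999999999996,424.93785529197078
1,1035.5512374114219
1.3999999999999999,1946.8605361464245
2,2775.9992377805265
2.2389999999999999,2845
3,2354.5729297893163
4.5,817.46437416189201
6.5,99.891317706661894
9,4.2185555582095127
12,0.062704978508564227
16,0.00015615936756858381
20,3.0041330637695635e-07
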