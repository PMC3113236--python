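concentration,response
0,1.1753025866296296
200,1.1725232722066214
400,1.153430133723466
600,1.1046076942007796
839.5,1
1000,0.90666199540000003
1250,0.74447319270381229
1500,0.5876512933148148
2000,0.34871615207692314
2500,0.20877085420394736
3000,0.13058917629218106
3300,0.10090166437410966
4000,0.058874155545454561
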