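concentration,response
0,0.76754733737194325
0.050000000000000003,0.83132686612023088
0.10000000000000001,0.8893082558914015
0.20999999999999999,1
0.40000000000000002,1.1502245098616692
0.69999999999999996,1.3190526741953719
1,1.4372323892289638
1.3999999999999999,1.5488465645384673
2,1.6604607398479703
3,1.7720749151574737
4.5,1.8633956040470676
6.5,1.9283347605907786
9,1.97298043071458
12,2.0038889715695194
16,2.0281309643969232
20,2.0431379123376967
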