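sex,covariate_value,L,M,S,c3,c10,c25,c50,c75,c90,c97
female,4,-1.1,37.566,0.248,22,27,31,34,38,41,44
female,5,-0.956,38.333,0.242,23,28,32,36,40,43,46
male,6,1.378,36.715,0.263,14,23,30,37,43,49,55
female,6,-0.717,39.568,0.234,25,30,34,39,42,46,50
male,7,1.378,38.61,0.246,17,25,32,39,45,51,56
female,7,-0.478,40.739,0.225,26,32,36,41,45,49,53
male,8,1.378,40.291,0.229,20,27,34,40,46,52,57
female,8,-0.239,41.934,0.217,28,33,38,43,47,51,55
male,9,1.378,41.762,0.212,22,29,36,42,48,53,58
female,9,0.0,43.072,0.208,28,34,39,44,48,52,56
male,10,1.378,43.375,0.197,25,31,38,43,49,54,59
female,10,0.239,43.953,0.199,28,34,39,44,48,52,56
male,11,1.378,45.12,0.183,27,34,39,45,51,56,61
female,11,0.478,44.548,0.191,29,34,39,44,48,53,57
male,12,1.378,46.671,0.171,29,35,41,47,52,57,62
female,12,0.717,45.08,0.182,29,35,40,45,49,53,58
male,13,1.378,47.784,0.161,31,37,43,48,53,58,62
female,13,0.956,45.636,0.173,30,35,41,45,50,54,59
male,14,1.378,48.331,0.152,33,38,43,48,53,58,62
female,14,1.195,46.118,0.165,30,36,41,46,51,56,60
male,15,1.378,48.581,0.142,34,39,44,49,53,57,62
female,15,1.434,46.07,0.156,30,36,42,47,51,56,60
male,16,1.378,49.112,0.131,36,40,45,49,53,57,61
female,16,1.673,45.343,0.148,30,35,41,45,50,55,59
male,17,1.378,50.353,0.12,38,42,46,50,54,58,62
female,17,1.912,44.258,0.139,29,34,39,44,48,53,57
male,18,1.378,52.583,0.111,40,45,49,53,56,60,64
female,18,2.151,43.116,0.13,27,33,38,42,47,51,55
male,19,1.378,55.86,0.103,44,48,52,56,60,63,67
male,20,1.378,59.928,0.097,48,52,56,60,64,67,71
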