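sex,covariate_value,L,M,S,c3,c10,c25,c50,c75,c90,c97
female,4,0.889,47.196,0.328,18,27,37,47,58,68,79
female,5,0.774,47.386,0.318,20,28,38,47,58,68,80
male,6,1.806,33.342,0.191,20,25,32,39,47,57,68
female,6,0.587,47.733,0.302,23,30,39,48,58,69,80
male,7,1.806,48.385,0.203,22,28,36,43,52,61,71
female,7,0.421,48.181,0.284,25,32,40,48,58,68,80
male,8,1.806,51.247,0.205,24,31,39,47,55,64,73
female,8,0.266,48.837,0.265,28,34,41,49,58,68,80
male,9,1.806,51.742,0.205,26,34,42,49,58,66,74
female,9,0.106,49.868,0.244,30,36,42,50,59,69,80
male,10,1.806,52.579,0.204,28,36,44,52,60,68,75
female,10,-0.033,51.098,0.221,33,38,44,51,59,69,80
male,11,1.806,54.891,0.2,30,39,47,54,62,69,76
female,11,-0.071,52.283,0.197,35,40,46,52,60,68,78
male,12,1.806,56.348,0.197,32,41,49,57,64,71,77
female,12,0.029,53.388,0.175,38,42,48,53,60,67,76
male,13,1.806,57.83,0.193,33,43,51,59,66,72,78
female,13,0.262,54.329,0.157,39,44,49,54,60,67,73
male,14,1.806,59.473,0.188,34,45,53,61,67,74,79
female,14,0.595,55.205,0.147,40,45,50,55,61,66,72
male,15,1.806,61.042,0.181,35,47,56,63,69,75,80
female,15,0.991,55.815,0.145,40,45,50,56,61,67,72
male,16,1.806,63.114,0.171,37,49,58,65,71,76,81
female,16,1.419,56.153,0.148,38,45,50,56,62,67,72
male,17,1.806,64.322,0.161,38,51,60,67,73,78,82
female,17,1.852,56.47,0.155,36,43,50,56,62,67,72
male,18,1.806,66.227,0.145,40,53,62,69,74,79,84
female,18,2.276,57.0,0.164,31,42,50,57,63,68,73
male,19,1.806,72.157,0.11,43,56,64,71,76,81,85
male,20,1.806,77.498,0.064,45,58,66,72,78,82,86
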