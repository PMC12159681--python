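sex,covariate_value,L,M,S
male,0.0,1.4844,3.4147,0.2122
female,0.0,-1.5196,2.7808,0.1468
male,1.0,1.4844,3.4367,0.2122
female,1.0,-1.5196,2.8144,0.1469
male,2.0,1.4844,3.4587,0.2122
female,2.0,-1.5196,2.8481,0.1469
male,3.0,1.4844,3.4808,0.2122
female,3.0,-1.5196,2.8817,0.1469
male,4.0,1.4844,3.5028,0.2122
female,4.0,-1.5196,2.9154,0.147
male,5.0,1.4844,3.5248,0.2122
female,5.0,-1.5196,2.949,0.147
male,6.0,1.4844,3.5469,0.2122
female,6.0,-1.5196,2.9827,0.147
male,7.0,1.4844,3.5689,0.2122
female,7.0,-1.5196,3.0163,0.147
male,8.0,1.4844,3.5909,0.2122
female,8.0,-1.5196,3.0499,0.1471
male,9.0,1.4844,3.6129,0.2122
female,9.0,-1.5196,3.0836,0.1471
male,10.0,1.4844,3.635,0.2122
female,10.0,-1.5196,3.1172,0.1471
male,11.0,1.4844,3.657,0.2122
female,11.0,-1.5196,3.1509,0.1471
male,12.0,1.4844,3.679,0.2122
female,12.0,-1.5196,3.1845,0.1472
male,13.0,1.4844,3.7011,0.2122
female,13.0,-1.5196,3.2182,0.1472
male,14.0,1.4844,3.7231,0.2122
female,14.0,-1.5196,3.2518,0.1472
male,15.0,1.4844,3.7451,0.2122
female,15.0,-1.5196,3.2855,0.1473
male,16.0,1.4844,3.7672,0.2122
female,16.0,-1.5196,3.3192,0.1473
male,17.0,1.4844,3.7892,0.2122
female,17.0,-1.5196,3.3528,0.1473
male,18.0,1.4844,3.8112,0.2122
female,18.0,-1.5196,3.3865,0.1473
male,19.0,1.4844,3.8333,0.2122
female,19.0,-1.5196,3.4201,0.1474
male,20.0,1.4844,3.8553,0.2122
female,20.0,-1.5196,3.4538,0.1474
male,21.0,1.4844,3.8773,0.2122
female,21.0,-1.5196,3.4875,0.1474
male,22.0,1.4844,3.8994,0.2122
female,22.0,-1.5196,3.5211,0.1475
male,23.0,1.4844,3.9214,0.2122
female,23.0,-1.5196,3.5548,0.1475
male,24.0,1.4844,3.9434,0.2122
female,24.0,-1.5196,3.5885,0.1475
male,25.0,1.4844,3.9655,0.2122
female,25.0,-1.5196,3.6221,0.1476
male,26.0,1.4844,3.9875,0.2122
female,26.0,-1.5196,3.6558,0.1476
male,27.0,1.4844,4.0096,0.2122
female,27.0,-1.5196,3.6895,0.1476
male,28.0,1.4844,4.0316,0.2122
female,28.0,-1.5196,3.7231,0.1476
male,29.0,1.4844,4.0536,0.2122
female,29.0,-1.5196,3.7568,0.1477
male,30.0,1.4844,4.0757,0.2122
female,30.0,-1.5196,3.7905,0.1477
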