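sex,covariate_value,L,M,S
male,0.0,-0.1879,12.3602,0.368
female,0.0,-0.0721,12.7303,0.2388
male,1.0,-0.1879,11.922,0.368
female,1.0,-0.0721,12.5028,0.2396
male,2.0,-0.1879,11.4838,0.368
female,2.0,-0.0721,12.2753,0.2403
male,3.0,-0.1879,11.0456,0.368
female,3.0,-0.0721,12.0477,0.2411
male,4.0,-0.1879,10.6075,0.368
female,4.0,-0.0721,11.8176,0.2419
male,5.0,-0.1879,10.17,0.368
female,5.0,-0.0721,11.5817,0.2427
male,6.0,-0.1879,9.7343,0.368
female,6.0,-0.0721,11.3421,0.2435
male,7.0,-0.1879,9.299,0.368
female,7.0,-0.0721,11.1121,0.2443
male,8.0,-0.1879,8.8602,0.368
female,8.0,-0.0721,10.9051,0.2451
male,9.0,-0.1879,8.4151,0.368
female,9.0,-0.0721,10.729,0.2459
male,10.0,-0.1879,7.9776,0.368
female,10.0,-0.0721,10.5679,0.2467
male,11.0,-0.1879,7.5683,0.368
female,11.0,-0.0721,10.3851,0.2474
male,12.0,-0.1879,7.2051,0.368
female,12.0,-0.0721,10.1582,0.2482
male,13.0,-0.1879,6.903,0.368
female,13.0,-0.0721,9.8884,0.249
male,14.0,-0.1879,6.6697,0.368
female,14.0,-0.0721,9.5911,0.2498
male,15.0,-0.1879,6.5089,0.368
female,15.0,-0.0721,9.2905,0.2506
male,16.0,-0.1879,6.4138,0.368
female,16.0,-0.0721,9.0033,0.2514
male,17.0,-0.1879,6.3729,0.368
female,17.0,-0.0721,8.7345,0.2522
male,18.0,-0.1879,6.3745,0.368
female,18.0,-0.0721,8.485,0.2529
male,19.0,-0.1879,6.4062,0.368
female,19.0,-0.0721,8.2574,0.2537
male,20.0,-0.1879,6.4551,0.368
female,20.0,-0.0721,8.0546,0.2545
male,21.0,-0.1879,6.5111,0.368
female,21.0,-0.0721,7.8749,0.2553
male,22.0,-0.1879,6.5646,0.368
female,22.0,-0.0721,7.7106,0.2561
male,23.0,-0.1879,6.6062,0.368
female,23.0,-0.0721,7.5479,0.2569
male,24.0,-0.1879,6.6277,0.368
female,24.0,-0.0721,7.3842,0.2577
male,25.0,-0.1879,6.6242,0.368
female,25.0,-0.0721,7.2113,0.2584
male,26.0,-0.1879,6.5975,0.368
female,26.0,-0.0721,7.0343,0.2592
male,27.0,-0.1879,6.5577,0.368
female,27.0,-0.0721,6.8647,0.26
male,28.0,-0.1879,6.5116,0.368
female,28.0,-0.0721,6.6951,0.2608
male,29.0,-0.1879,6.4643,0.368
female,29.0,-0.0721,6.525,0.2616
male,30.0,-0.1879,6.417,0.368
female,30.0,-0.0721,6.355,0.2624
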