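digit,step,x,y
0,1,0.500000,0.920000
0,2,0.391261,0.883154
0,3,0.307685,0.803516
0,4,0.254795,0.700156
0,5,0.227644,0.587092
0,6,0.222548,0.470969
0,7,0.239280,0.356026
0,8,0.279406,0.247202
0,9,0.345911,0.152486
0,10,0.442819,0.091292
0,11,0.557181,0.091292
0,12,0.654089,0.152486
0,13,0.720594,0.247202
0,14,0.760720,0.356026
0,15,0.777452,0.470969
0,16,0.772356,0.587092
0,17,0.745205,0.700156
0,18,0.692315,0.803516
0,19,0.608739,0.883154
0,20,0.500000,0.920000
1,1,0.350000,0.720000
1,2,0.387103,0.770198
1,3,0.424205,0.820396
1,4,0.461308,0.870593
1,5,0.498411,0.920791
1,6,0.520000,0.923900
1,7,0.520000,0.861478
1,8,0.520000,0.799057
1,9,0.520000,0.736636
1,10,0.520000,0.674214
1,11,0.520000,0.611793
1,12,0.520000,0.549371
1,13,0.520000,0.486950
1,14,0.520000,0.424529
1,15,0.520000,0.362107
1,16,0.520000,0.299686
1,17,0.520000,0.237264
1,18,0.520000,0.174843
1,19,0.520000,0.112421
1,20,0.520000,0.050000
2,1,0.220000,0.780000
2,2,0.299575,0.864548
2,3,0.379150,0.949097
2,4,0.494866,0.950000
2,5,0.610972,0.950000
2,6,0.686891,0.866386
2,7,0.759422,0.775723
2,8,0.728047,0.685059
2,9,0.655516,0.594396
2,10,0.582986,0.503732
2,11,0.510455,0.413068
2,12,0.437924,0.322405
2,13,0.365393,0.231741
2,14,0.292862,0.141078
2,15,0.220331,0.050414
2,16,0.335576,0.050000
2,17,0.451682,0.050000
2,18,0.567788,0.050000
2,19,0.683894,0.050000
2,20,0.800000,0.050000
3,1,0.250000,0.900000
3,2,0.353807,0.900000
3,3,0.457614,0.900000
3,4,0.561420,0.900000
3,5,0.665227,0.900000
3,6,0.659875,0.843825
3,7,0.599538,0.759354
3,8,0.539202,0.674883
3,9,0.478866,0.590412
3,10,0.497107,0.523306
3,11,0.587421,0.472128
3,12,0.677735,0.420950
3,13,0.742192,0.360779
3,14,0.703121,0.264606
3,15,0.664051,0.168433
3,16,0.624980,0.072259
3,17,0.529875,0.069013
3,18,0.426583,0.079342
3,19,0.323292,0.089671
3,20,0.220000,0.100000
4,1,0.680000,0.050000
4,2,0.680000,0.170799
4,3,0.680000,0.291598
4,4,0.680000,0.412398
4,5,0.680000,0.533197
4,6,0.680000,0.653996
4,7,0.680000,0.774795
4,8,0.680000,0.895594
4,9,0.637234,0.899215
4,10,0.559423,0.806814
4,11,0.481611,0.714414
4,12,0.403800,0.622013
4,13,0.325989,0.529612
4,14,0.248178,0.437212
4,15,0.246004,0.380000
4,16,0.366803,0.380000
4,17,0.487602,0.380000
4,18,0.608402,0.380000
4,19,0.729201,0.380000
4,20,0.850000,0.380000
5,1,0.780000,0.950000
5,2,0.658191,0.950000
5,3,0.536381,0.950000
5,4,0.414572,0.950000
5,5,0.292762,0.950000
5,6,0.264654,0.851097
5,7,0.258079,0.729465
5,8,0.251505,0.607833
5,9,0.343328,0.590666
5,10,0.464350,0.604497
5,11,0.585371,0.618328
5,12,0.668554,0.537735
5,13,0.746535,0.444158
5,14,0.780152,0.347251
5,15,0.717018,0.243080
5,16,0.653884,0.138908
5,17,0.582305,0.052328
5,18,0.461537,0.068219
5,19,0.340768,0.084109
5,20,0.220000,0.100000
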