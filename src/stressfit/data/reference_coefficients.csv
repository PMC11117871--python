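kind,vertebra,experiment,direction,c0,c1,c2,c3,d2,d1,d0,r_squared
stress,L3,1,load,0.1133,7.163,1.4699,3.2392,,,,0.999
stress,L3,1,unload,-0.047,7.6214,3.1659,4.2821,,,,0.9998
stress,L3,2,load,0.8875,10.1438,0.8824,2.9998,,,,0.9934
stress,L3,2,unload,0.0057,6.9451,4.0148,3.6638,,,,0.9993
stress,L3,3,load,-2.4883,13.204,22.166,0.932,,,,0.9992
stress,L4,1,load,0.0467,7.1418,26.6721,0.2254,,,,0.9996
stress,L4,1,unload,-0.0518,7.6406,34.3704,0.2986,,,,0.9998
stress,L4,2,load,0.0107,6.0252,3.2338,2.6063,,,,0.9989
stress,L4,2,unload,-0.2039,7.7396,3.5797,3.4333,,,,0.9995
stress,L4,3,load,-0.7793,24.651,17.5473,0.8189,,,,0.9966
stress,L5,1,load,0.0356,6.3102,242.6306,0.0292,,,,0.9995
stress,L5,1,unload,-0.0566,5.7441,296.3236,0.0453,,,,0.9994
stress,L5,2,load,0.2138,7.3233,1.794,2.1683,,,,0.9996
stress,L5,2,unload,-0.0584,7.0522,3.827,3.1042,,,,0.9994
stress,L5,3,load,-4.3779,33.41,9.1167,0.7886,,,,0.9996
stretch,L3,1,down,,,,,-0.00002,-0.4544,1.00016,0.99999
stretch,L3,1,up,,,,,0.00055,0.039999,0.64854,0.99993
stretch,L3,2,down,,,,,-0.00006,-0.04981,1.00012,0.99999
stretch,L3,2,up,,,,,0.00149,0.03695,0.68887,0.99941
stretch,L4,1,down,,,,,0.02194,-0.45941,1.0009,0.99988
stretch,L4,1,up,,,,,0.03257,0.43083,0.75964,0.99998
stretch,L4,2,down,,,,,0.00041,-0.05105,1.00035,0.99991
stretch,L4,2,up,,,,,-0.00201,0.06462,0.65712,0.99907
stretch,L5,1,down,,,,,-21.63102,-3.04609,1.00823,0.99321
stretch,L5,1,up,,,,,42.69855,-0.83142,0.84651,0.99158
stretch,L5,2,down,,,,,0.00013,-0.05029,1.0002,0.99999
stretch,L5,2,up,,,,,0.00051,0.04624,0.72708,0.99998
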