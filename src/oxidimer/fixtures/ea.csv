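form,compound,phase,value,ion_optimized_in_water,table
M,2AP,gas,-17.431,0,5
M,L3HOK,gas,7.141,0,5
M,3HAA,gas,1.481,0,5
M,3HAAi,gas,-74.436,0,5
M,2AP,heptane,-0.072,0,5
M,L3HOK,heptane,29.794,0,5
M,3HAA,heptane,25.565,0,5
M,3HAAi,heptane,-32.667,0,5
M,2AP,water,24.818,0,5
M,L3HOK,water,55.874,0,5
M,3HAA,water,51.965,0,5
M,3HAAi,water,16.333,0,5
Mstar,2AP,gas,36.773,0,5
Mstar,L3HOK,gas,46.724,0,5
Mstar,3HAA,gas,49.904,1,5
Mstar,3HAAi,gas,-43.573,0,5
Mstar,2AP,heptane,59.400,0,5
Mstar,L3HOK,heptane,66.802,0,5
Mstar,3HAA,heptane,70.871,1,5
Mstar,3HAAi,heptane,17.558,0,5
Mstar,2AP,water,87.370,0,5
Mstar,L3HOK,water,92.202,0,5
Mstar,3HAA,water,97.041,1,5
Mstar,3HAAi,water,85.938,0,5
Mq,2AP,gas,40.629,0,5
Mq,L3HOK,gas,56.762,0,5
Mq,3HAA,gas,52.249,0,5
Mq,3HAAi,gas,-41.936,0,5
Mq,2AP,heptane,66.755,0,5
Mq,L3HOK,heptane,77.456,0,5
Mq,3HAA,heptane,75.648,0,5
Mq,3HAAi,heptane,22.861,0,5
Mq,2AP,water,93.995,0,5
Mq,L3HOK,water,98.566,0,5
Mq,3HAA,water,99.678,0,5
Mq,3HAAi,water,90.601,0,5
D1,2AP,gas,15.388,0,5
D1,L3HOK,gas,39.966,0,5
D1,3HAA,gas,41.352,0,5
D1,3HAAi,gas,-106.854,0,5
D1,2AP,heptane,38.580,0,5
D1,L3HOK,heptane,58.428,0,5
D1,3HAA,heptane,60.527,0,5
D1,3HAAi,heptane,-22.479,0,5
D1,2AP,water,64.880,0,5
D1,L3HOK,water,77.958,0,5
D1,3HAA,water,80.177,0,5
D1,3HAAi,water,66.781,0,5
D2,2AP,gas,-10.561,0,5
D2,L3HOK,gas,22.615,0,5
D2,3HAA,gas,13.775,0,5
D2,3HAAi,gas,-109.852,1,5
D2,2AP,heptane,4.591,0,5
D2,L3HOK,heptane,40.390,0,5
D2,3HAA,heptane,33.802,0,5
D2,3HAAi,heptane,-48.200,1,5
D2,2AP,water,26.731,0,5
D2,L3HOK,water,59.440,0,5
D2,3HAA,water,56.422,0,5
D2,3HAAi,water,30.310,1,5
D3,2AP,gas,33.655,0,5
D3,L3HOK,gas,47.391,0,5
D3,3HAA,gas,42.839,0,5
D3,3HAAi,gas,-90.037,0,5
D3,2AP,heptane,53.346,0,5
D3,L3HOK,heptane,62.764,0,5
D3,3HAA,heptane,60.205,0,5
D3,3HAAi,heptane,-9.404,0,5
D3,2AP,water,79.336,0,5
D3,L3HOK,water,82.734,0,5
D3,3HAA,water,83.125,0,5
D3,3HAAi,water,79.486,0,5
D4,2AP,gas,36.309,0,5
D4,L3HOK,gas,54.684,0,5
D4,3HAA,gas,47.059,0,5
D4,3HAAi,gas,-92.084,0,5
D4,2AP,heptane,60.025,0,5
D4,L3HOK,heptane,72.552,0,5
D4,3HAA,heptane,67.666,0,5
D4,3HAAi,heptane,-6.092,0,5
D4,2AP,water,86.635,0,5
D4,L3HOK,water,71.732,0,5
D4,3HAA,water,90.486,0,5
D4,3HAAi,water,85.608,0,5
D5,2AP,gas,39.123,0,5
D5,L3HOK,gas,52.428,0,5
D5,3HAA,gas,55.737,0,5
D5,3HAAi,gas,-90.281,0,5
D5,2AP,heptane,61.768,0,5
D5,L3HOK,heptane,70.691,0,5
D5,3HAA,heptane,74.807,0,5
D5,3HAAi,heptane,-5.238,0,5
D5,2AP,water,87.248,0,5
D5,L3HOK,water,91.141,0,5
D5,3HAA,water,94.557,0,5
D5,3HAAi,water,85.722,0,5
D6,2AP,gas,17.741,0,5
D6,L3HOK,gas,41.744,0,5
D6,3HAA,gas,31.103,0,5
D6,3HAAi,gas,-104.878,0,5
D6,2AP,heptane,39.556,0,5
D6,L3HOK,heptane,57.051,0,5
D6,3HAA,heptane,50.309,0,5
D6,3HAAi,heptane,-5.908,0,5
D6,2AP,water,63.466,0,5
D6,L3HOK,water,72.411,0,5
D6,3HAA,water,71.039,0,5
D6,3HAAi,water,59.572,0,5
D7,2AP,gas,-11.311,0,5
D7,L3HOK,gas,25.482,0,5
D7,3HAA,gas,16.666,0,5
D7,3HAAi,gas,-108.281,1,5
D7,2AP,heptane,4.698,0,5
D7,L3HOK,heptane,42.627,0,5
D7,3HAA,heptane,36.352,0,5
D7,3HAAi,heptane,-46.753,1,5
D7,2AP,water,27.128,0,5
D7,L3HOK,water,61.107,0,5
D7,3HAA,water,57.402,0,5
D7,3HAAi,water,28.397,1,5
D8,2AP,gas,35.010,0,5
D8,L3HOK,gas,50.540,0,5
D8,3HAA,gas,46.310,0,5
D8,3HAAi,gas,-96.759,0,5
D8,2AP,heptane,53.907,0,5
D8,L3HOK,heptane,65.201,0,5
D8,3HAA,heptane,62.897,0,5
D8,3HAAi,heptane,-14.847,0,5
D8,2AP,water,78.207,0,5
D8,L3HOK,water,84.581,0,5
D8,3HAA,water,84.057,0,5
D8,3HAAi,water,75.203,0,5
D9,2AP,gas,36.472,0,5
D9,L3HOK,gas,52.328,0,5
D9,3HAA,gas,48.910,0,5
D9,3HAAi,gas,-96.318,0,5
D9,2AP,heptane,59.149,0,5
D9,L3HOK,heptane,70.003,0,5
D9,3HAA,heptane,68.486,0,5
D9,3HAAi,heptane,-10.766,0,5
D9,2AP,water,83.819,0,5
D9,L3HOK,water,86.873,0,5
D9,3HAA,water,89.126,0,5
D9,3HAAi,water,78.984,0,5
D10,2AP,gas,37.870,0,5
D10,L3HOK,gas,51.532,0,5
D10,3HAA,gas,49.163,0,5
D10,3HAAi,gas,-90.484,0,5
D10,2AP,heptane,60.674,0,5
D10,L3HOK,heptane,68.895,0,5
D10,3HAA,heptane,68.277,0,5
D10,3HAAi,heptane,-6.589,0,5
D10,2AP,water,84.684,0,5
D10,L3HOK,water,87.875,0,5
D10,3HAA,water,89.017,0,5
D10,3HAAi,water,81.701,0,5
D1p,2AP,gas,49.739,0,5
D1p,L3HOK,gas,61.771,0,5
D1p,3HAA,gas,56.314,0,5
D1p,3HAAi,gas,-86.567,0,5
D1p,2AP,heptane,71.139,0,5
D1p,L3HOK,heptane,77.774,0,5
D1p,3HAA,heptane,68.723,0,5
D1p,3HAAi,heptane,-2.120,0,5
D1p,2AP,water,93.579,0,5
D1p,L3HOK,water,94.794,0,5
D1p,3HAA,water,97.113,0,5
D1p,3HAAi,water,86.860,0,5
D3p,2AP,gas,68.794,0,5
D3p,L3HOK,gas,68.297,0,5
D3p,3HAA,gas,63.722,0,5
D3p,3HAAi,gas,-82.331,0,5
D3p,2AP,heptane,86.455,0,5
D3p,L3HOK,heptane,82.723,0,5
D3p,3HAA,heptane,79.801,0,5
D3p,3HAAi,heptane,-2.200,0,5
D3p,2AP,water,107.455,0,5
D3p,L3HOK,water,100.673,0,5
D3p,3HAA,water,99.551,0,5
D3p,3HAAi,water,87.080,0,5
XAN,L3HOK,gas,63.213,0,5
XAN,L3HOK,heptane,81.117,0,5
XAN,L3HOK,water,98.097,0,5
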