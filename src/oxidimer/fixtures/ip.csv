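form,compound,phase,value,ion_optimized_in_water,table
M,2AP,gas,164.117,0,4
M,L3HOK,gas,162.258,0,4
M,3HAA,gas,169.726,0,4
M,3HAAi,gas,74.475,1,4
M,2AP,heptane,138.501,0,4
M,L3HOK,heptane,140.417,0,4
M,3HAA,heptane,144.833,0,4
M,3HAAi,heptane,107.384,1,4
M,2AP,water,115.721,0,4
M,L3HOK,water,120.737,0,4
M,3HAA,water,121.873,0,4
M,3HAAi,water,130.254,1,4
Mstar,2AP,gas,169.569,0,4
Mstar,L3HOK,gas,164.544,0,4
Mstar,3HAA,gas,173.667,0,4
Mstar,3HAAi,gas,109.935,1,4
Mstar,2AP,heptane,147.295,0,4
Mstar,L3HOK,heptane,145.826,0,4
Mstar,3HAA,heptane,151.607,0,4
Mstar,3HAAi,heptane,101.612,1,4
Mstar,2AP,water,122.955,0,4
Mstar,L3HOK,water,124.966,0,4
Mstar,3HAA,water,126.967,0,4
Mstar,3HAAi,water,119.232,1,4
Mq,2AP,gas,225.274,1,4
Mq,L3HOK,gas,187.688,0,4
Mq,3HAA,gas,206.433,0,4
Mq,3HAAi,gas,106.970,0,4
Mq,2AP,heptane,182.763,1,4
Mq,L3HOK,heptane,163.596,0,4
Mq,3HAA,heptane,181.238,0,4
Mq,3HAAi,heptane,127.181,0,4
Mq,2AP,water,155.263,1,4
Mq,L3HOK,water,141.026,0,4
Mq,3HAA,water,157.728,0,4
Mq,3HAAi,water,150.671,0,4
D1,2AP,gas,156.054,0,4
D1,L3HOK,gas,162.435,0,4
D1,3HAA,gas,161.459,0,4
D1,3HAAi,gas,30.600,1,4
D1,2AP,heptane,134.580,0,4
D1,L3HOK,heptane,142.910,0,4
D1,3HAA,heptane,140.259,0,4
D1,3HAAi,heptane,43.143,1,4
D1,2AP,water,115.420,0,4
D1,L3HOK,water,123.090,0,4
D1,3HAA,water,120.459,0,4
D1,3HAAi,water,118.883,1,4
D2,2AP,gas,142.385,0,4
D2,L3HOK,gas,150.010,0,4
D2,3HAA,gas,146.307,0,4
D2,3HAAi,gas,1.699,0,4
D2,2AP,heptane,122.551,0,4
D2,L3HOK,heptane,129.424,0,4
D2,3HAA,heptane,126.682,0,4
D2,3HAAi,heptane,52.704,0,4
D2,2AP,water,106.381,0,4
D2,L3HOK,water,111.004,0,4
D2,3HAA,water,109.632,0,4
D2,3HAAi,water,111.186,0,4
D3,2AP,gas,139.983,0,4
D3,L3HOK,gas,146.549,0,4
D3,3HAA,gas,144.102,0,4
D3,3HAAi,gas,0.957,1,4
D3,2AP,heptane,123.507,0,4
D3,L3HOK,heptane,130.270,0,4
D3,3HAA,heptane,127.607,0,4
D3,3HAAi,heptane,51.781,1,4
D3,2AP,water,107.087,0,4
D3,L3HOK,water,112.580,0,4
D3,3HAA,water,110.387,0,4
D3,3HAAi,water,103.471,1,4
D4,2AP,gas,166.378,0,4
D4,L3HOK,gas,169.757,0,4
D4,3HAA,gas,172.613,0,4
D4,3HAAi,gas,20.420,0,4
D4,2AP,heptane,143.980,0,4
D4,L3HOK,heptane,151.663,0,4
D4,3HAA,heptane,152.408,0,4
D4,3HAAi,heptane,69.743,0,4
D4,2AP,water,123.160,0,4
D4,L3HOK,water,136.193,0,4
D4,3HAA,water,133.798,0,4
D4,3HAAi,water,124.433,0,4
D5,2AP,gas,159.845,0,4
D5,L3HOK,gas,165.277,0,4
D5,3HAA,gas,165.407,0,4
D5,3HAAi,gas,14.903,0,4
D5,2AP,heptane,139.689,0,4
D5,L3HOK,heptane,145.243,0,4
D5,3HAA,heptane,145.302,0,4
D5,3HAAi,heptane,63.685,0,4
D5,2AP,water,122.109,0,4
D5,L3HOK,water,125.553,0,4
D5,3HAA,water,127.202,0,4
D5,3HAAi,water,117.805,0,4
D6,2AP,gas,151.876,0,4
D6,L3HOK,gas,160.487,0,4
D6,3HAA,gas,161.285,0,4
D6,3HAAi,gas,12.474,1,4
D6,2AP,heptane,131.272,0,4
D6,L3HOK,heptane,143.122,0,4
D6,3HAA,heptane,140.982,0,4
D6,3HAAi,heptane,59.322,1,4
D6,2AP,water,113.532,0,4
D6,L3HOK,water,127.202,0,4
D6,3HAA,water,123.182,0,4
D6,3HAAi,water,107.582,0,4
D7,2AP,gas,137.538,0,4
D7,L3HOK,gas,141.940,0,4
D7,3HAA,gas,142.197,0,4
D7,3HAAi,gas,-3.135,0,4
D7,2AP,heptane,117.519,0,4
D7,L3HOK,heptane,123.958,0,4
D7,3HAA,heptane,122.506,0,4
D7,3HAAi,heptane,43.822,0,4
D7,2AP,water,100.099,0,4
D7,L3HOK,water,107.858,0,4
D7,3HAA,water,104.706,0,4
D7,3HAAi,water,94.892,0,4
D8,2AP,gas,140.693,0,4
D8,L3HOK,gas,142.364,0,4
D8,3HAA,gas,145.311,0,4
D8,3HAAi,gas,2.965,1,4
D8,2AP,heptane,123.214,0,4
D8,L3HOK,heptane,112.536,0,4
D8,3HAA,heptane,127.942,0,4
D8,3HAAi,heptane,51.915,1,4
D8,2AP,water,104.534,0,4
D8,L3HOK,water,110.976,0,4
D8,3HAA,water,108.902,0,4
D8,3HAAi,water,99.715,1,4
D9,2AP,gas,173.081,0,4
D9,L3HOK,gas,174.437,0,4
D9,3HAA,gas,180.871,0,4
D9,3HAAi,gas,24.029,1,4
D9,2AP,heptane,150.194,0,4
D9,L3HOK,heptane,155.376,0,4
D9,3HAA,heptane,159.439,0,4
D9,3HAAi,heptane,71.278,1,4
D9,2AP,water,127.244,0,4
D9,L3HOK,water,139.246,0,4
D9,3HAA,water,138.649,0,4
D9,3HAAi,water,121.068,1,4
D10,2AP,gas,170.510,0,4
D10,L3HOK,gas,168.494,0,4
D10,3HAA,gas,177.467,0,4
D10,3HAAi,gas,15.375,0,4
D10,2AP,heptane,149.212,0,4
D10,L3HOK,heptane,148.562,0,4
D10,3HAA,heptane,156.456,0,4
D10,3HAAi,heptane,64.426,0,4
D10,2AP,water,128.922,0,4
D10,L3HOK,water,130.882,0,4
D10,3HAA,water,136.526,0,4
D10,3HAAi,water,117.186,0,4
D1p,2AP,gas,170.472,0,4
D1p,L3HOK,gas,171.145,0,4
D1p,3HAA,gas,178.118,0,4
D1p,3HAAi,gas,19.180,0,4
D1p,2AP,heptane,148.452,0,4
D1p,L3HOK,heptane,152.327,0,4
D1p,3HAA,heptane,157.187,0,4
D1p,3HAAi,heptane,68.410,0,4
D1p,2AP,water,128.142,0,4
D1p,L3HOK,water,134.087,0,4
D1p,3HAA,water,138.877,0,4
D1p,3HAAi,water,126.490,0,4
D3p,2AP,gas,145.886,0,4
D3p,L3HOK,gas,152.647,0,4
D3p,3HAA,gas,154.275,0,4
D3p,3HAAi,gas,12.897,0,4
D3p,2AP,heptane,129.193,0,4
D3p,L3HOK,heptane,138.120,0,4
D3p,3HAA,heptane,137.437,0,4
D3p,3HAAi,heptane,64.334,0,4
D3p,2AP,water,110.863,0,4
D3p,L3HOK,water,122.410,0,4
D3p,3HAA,water,119.677,0,4
D3p,3HAAi,water,116.354,0,4
XAN,L3HOK,gas,178.983,0,4
XAN,L3HOK,heptane,158.372,0,4
XAN,L3HOK,water,140.052,0,4
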