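compound,form,nu_i,phase,dG_TS_R,dG_TS_P,k_fwd_printed,k_rev_printed,table
2AP,D1p,1702.2,gas,21.684,28.246,7.33e-02,1.13e-06,6
2AP,D1p,1702.2,heptane,20.512,26.957,5.30e-01,1.00e-05,6
2AP,D1p,1702.2,water,19.152,26.707,5.26e+00,1.52e-05,6
2AP,D2p,1426.7,gas,15.754,9.478,1.27e+03,5.07e+07,6
2AP,D2p,1426.7,heptane,15.270,9.095,2.88e+03,9.68e+07,6
2AP,D2p,1426.7,water,13.260,7.645,8.57e+04,1.12e+09,6
2AP,D5p,2297.8,gas,33.439,21.308,2.85e-10,2.22e-01,6
2AP,D5p,2297.8,heptane,32.729,21.308,9.43e-10,2.22e-01,6
2AP,D5p,2297.8,water,30.819,22.218,2.37e-08,4.78e-02,6
L3HOK,D1p,1841.9,gas,26.384,28.168,2.96e-05,1.46e-06,6
L3HOK,D1p,1841.9,heptane,25.808,27.555,7.83e-05,4.10e-06,6
L3HOK,D1p,1841.9,water,23.568,27.695,3.43e-03,3.24e-06,6
L3HOK,D2p,1385.9,gas,15.373,16.224,2.33e+03,5.54e+02,6
L3HOK,D2p,1385.9,heptane,14.325,17.961,1.37e+04,2.95e+01,6
L3HOK,D2p,1385.9,water,13.665,15.141,4.16e+04,3.45e+03,6
L3HOK,D5p,2089.6,gas,34.355,21.234,5.19e-11,2.16e-01,6
L3HOK,D5p,2089.6,heptane,32.479,20.242,1.23e-09,1.15e+00,6
L3HOK,D5p,2089.6,water,31.459,20.112,6.88e-09,1.43e+00,6
3HAA,D1p,1883.6,gas,27.034,29.501,1.02e-05,1.59e-07,6
3HAA,D1p,1883.6,heptane,26.164,28.827,4.44e-05,4.96e-07,6
3HAA,D1p,1883.6,water,24.764,28.937,4.72e-04,4.12e-07,6
3HAA,D2p,1424.2,gas,15.283,8.012,2.81e+03,6.01e+08,6
3HAA,D2p,1424.2,heptane,14.452,8.240,1.14e+04,4.09e+08,6
3HAA,D2p,1424.2,water,13.272,7.890,8.37e+04,7.38e+08,6
3HAA,D5p,2071.5,gas,33.305,19.130,3.01e-10,7.41e+00,6
3HAA,D5p,2071.5,heptane,32.785,19.092,7.24e-10,7.89e+00,6
3HAA,D5p,2071.5,water,31.235,20.242,9.90e-09,1.13e+00,6
3HAAi,D1p,1706.1,gas,20.483,35.363,5.59e-01,6.91e-12,6
3HAAi,D1p,1706.1,heptane,20.682,33.797,3.99e-01,9.71e-11,6
3HAAi,D1p,1706.1,water,19.932,30.887,1.42e+00,1.32e-08,6
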