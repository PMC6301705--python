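phase,reduction,dG,table
gas,full,-416.754,3
gas,H2O2,-108.188,3
gas,HO2,-37.988,3
gas,superoxide,-13.945,3
heptane,full,-415.782,3
heptane,H2O2,-105.873,3
heptane,HO2,-37.687,3
heptane,superoxide,-85.83,3
water,full,-431.358,3
water,H2O2,-111.033,3
water,HO2,-41.477,3
water,superoxide,-87.31,3
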