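compound,phase,sum,table
2AP,gas,310.254,1
L3HOK,gas,317.589,1
3HAA,gas,325.738,1
3HAAi,gas,370.475,1
2AP,heptane,313.132,1
L3HOK,heptane,323.371,1
3HAA,heptane,329.303,1
3HAAi,heptane,352.421,1
2AP,water,319.672,1
L3HOK,water,330.631,1
3HAA,water,334.283,1
3HAAi,water,333.481,1
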