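phase,reduction,combo,compounds
gas,full,SUM,2AP|L3HOK|3HAA|3HAAi
gas,H2O2,N5+6,3HAAi
gas,H2O2,N11+12,L3HOK|3HAAi
gas,H2O2,N19+22,L3HOK
gas,HO2,N11,3HAAi
gas,HO2,N16,2AP|3HAAi
gas,HO2,N17,2AP|L3HOK|3HAA
gas,HO2,N19,L3HOK|3HAAi
gas,HO2,N21,2AP|L3HOK|3HAA|3HAAi
heptane,full,SUM,2AP|L3HOK|3HAA|3HAAi
heptane,H2O2,N11+12,3HAAi
heptane,H2O2,N19+22,L3HOK
heptane,HO2,N11,3HAAi
heptane,HO2,N16,2AP|3HAAi
heptane,HO2,N17,2AP|L3HOK|3HAA
heptane,HO2,N19,L3HOK|3HAAi
heptane,HO2,N21,2AP|L3HOK|3HAA|3HAAi
water,full,SUM,2AP|L3HOK|3HAA|3HAAi
water,H2O2,N11+12,L3HOK|3HAAi
water,H2O2,N26,L3HOK
water,HO2,N16,2AP|L3HOK|3HAA|3HAAi
water,HO2,N17,2AP|L3HOK|3HAA|3HAAi
water,HO2,N21,2AP|L3HOK|3HAA|3HAAi
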