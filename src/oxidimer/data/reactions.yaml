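# Stage registry for the oxidative dimerization network of 2-aminophenol-type
# monomers (2AP, L-3HOK, 3HAA, 3HAAi).
#
# Species forms (per compound unless listed under `shared`):
#   M        monomer (R-2AP)
#   Mstar    semiquinoneimine radical (R-2AP*)
#   Mq       quinoneimine (R-2APq)
#   D1..D10  intermediates of the "classic" (enzyme-assisted) pathway;
#            D10 is the phenoxazinone product (2APX analogue)
#   D4H, D9H protonated (NH2+) forms of D4 and D9
#   D1p..D6p intermediates of the non-enzymatic pathway (primed dimers;
#            ASCII "p" stands for the prime)
#   XAN      xanthommatin (L-3HOK only); XANi its deprotonated form
#   shared:  Hs (H atom), Hp (proton), NH3, NH4p
#
# classes: H_ABSTRACTION, CONJUGATION, TAUTOMERIZATION, PROTONATION,
#          DEPROTONATION, CYCLIZATION
reactions:
  - {id: N1,  rclass: H_ABSTRACTION,  reactants: {M: 1},          products: {Mstar: 1, Hs: 1}}
  - {id: N2,  rclass: H_ABSTRACTION,  reactants: {Mstar: 1},      products: {Mq: 1, Hs: 1}}
  - {id: N3,  rclass: CONJUGATION,    reactants: {M: 1, Mq: 1},   products: {D1: 1}}
  - {id: N4,  rclass: TAUTOMERIZATION, reactants: {D1: 1},        products: {D2: 1}}
  - {id: N5,  rclass: H_ABSTRACTION,  reactants: {D2: 1},         products: {D3: 1, Hs: 1}}
  - {id: N6,  rclass: H_ABSTRACTION,  reactants: {D3: 1},         products: {D4: 1, Hs: 1}}
  - {id: N7,  rclass: PROTONATION,    reactants: {D4: 1, Hp: 1},  products: {D4H: 1}}
  - {id: N8,  rclass: DEPROTONATION,  reactants: {D4H: 1},        products: {D5: 1, Hp: 1}}
  - {id: N9,  rclass: CYCLIZATION,    reactants: {D5: 1},         products: {D6: 1}}
  - {id: N10, rclass: TAUTOMERIZATION, reactants: {D6: 1},        products: {D7: 1}}
  - {id: N11, rclass: H_ABSTRACTION,  reactants: {D7: 1},         products: {D8: 1, Hs: 1}}
  - {id: N12, rclass: H_ABSTRACTION,  reactants: {D8: 1},         products: {D9: 1, Hs: 1}}
  - {id: N13, rclass: PROTONATION,    reactants: {D9: 1, Hp: 1},  products: {D9H: 1}}
  - {id: N14, rclass: DEPROTONATION,  reactants: {D9H: 1},        products: {D10: 1, Hp: 1}}
  - {id: N15, rclass: CONJUGATION,    reactants: {Mq: 2},         products: {D1p: 1}}
  - {id: N16, rclass: H_ABSTRACTION,  reactants: {D1p: 1},        products: {D3p: 1, Hs: 1}}
  - {id: N17, rclass: H_ABSTRACTION,  reactants: {D3p: 1},        products: {D10: 1, Hs: 1}}
  - {id: N18, rclass: TAUTOMERIZATION, reactants: {D1p: 1},       products: {D2p: 1}}
  - {id: N19, rclass: H_ABSTRACTION,  reactants: {D2p: 1},        products: {D3p: 1, Hs: 1}}
  - {id: N20, rclass: CYCLIZATION,    reactants: {D3p: 1},        products: {D5p: 1}}
  - {id: N21, rclass: H_ABSTRACTION,  reactants: {D5p: 1},        products: {D10: 1, Hs: 1}}
  - {id: N22, rclass: H_ABSTRACTION,  reactants: {D3p: 1},        products: {D4p: 1, Hs: 1}}
  - {id: N23, rclass: CYCLIZATION,    reactants: {D4p: 1},        products: {D6p: 1}}
  - {id: N24, rclass: TAUTOMERIZATION, reactants: {D6p: 1},       products: {D10: 1}}
  - {id: N25, rclass: TAUTOMERIZATION, reactants: {D5p: 1},       products: {D8: 1}}
  # Final xanthommatin stage, L-3HOK only, printed in two product variants.
  # The ammonium variant pairs NH4+ with deprotonated XAN so that charge is
  # conserved without a free proton (a heptane value is printed for it).
  - {id: N26, rclass: H_ABSTRACTION, variant: NH4, compounds: [L3HOK],
     reactants: {D10: 1}, products: {XANi: 1, NH4p: 1, Hs: 2}}
  - {id: N26, rclass: H_ABSTRACTION, variant: NH3, compounds: [L3HOK],
     reactants: {D10: 1}, products: {XAN: 1, NH3: 1, Hs: 2}}
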