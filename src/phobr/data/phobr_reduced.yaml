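model_id: phobr_reduced
volume_um3: 1.0
species:
- name: PhoR
  initial_concentration_uM: 1.0
  initial_copies: 602
- name: PhoRp
  initial_concentration_uM: 0.0
  initial_copies: 0
- name: PhoB
  initial_concentration_uM: 5.0
  initial_copies: 3011
- name: PhoBp
  initial_concentration_uM: 0.0
  initial_copies: 0
- name: DiPhoBpp
  initial_concentration_uM: 0.0
  initial_copies: 0
- name: pPhoA
  initial_concentration_uM: 0.016605390671738465
  initial_copies: 10
- name: pPhoAa
  initial_concentration_uM: 0.0
  initial_copies: 0
- name: pPhoB
  initial_concentration_uM: 0.016605390671738465
  initial_copies: 10
- name: pPhoBa
  initial_concentration_uM: 0.0
  initial_copies: 0
- name: PhoA
  initial_concentration_uM: 0.0
  initial_copies: 0
reactions:
- id: q01
  reactants:
    PhoR: 1
  products:
    PhoRp: 1
  rate: 0.05
  scaling_tag: fc
- id: q02
  reactants:
    PhoRp: 1
  products:
    PhoR: 1
  rate: 0.01
  scaling_tag: none
- id: q03
  reactants:
    PhoRp: 1
    PhoB: 1
  products:
    PhoR: 1
    PhoBp: 1
  rate: 0.06666666666666667
  scaling_tag: none
- id: q04
  reactants:
    PhoR: 1
    PhoBp: 1
  products:
    PhoR: 1
    PhoB: 1
  rate: 0.03333333333333333
  scaling_tag: none
- id: q05
  reactants:
    PhoBp: 2
  products:
    DiPhoBpp: 1
  rate: 0.2
  scaling_tag: none
- id: q06
  reactants:
    DiPhoBpp: 1
  products:
    PhoBp: 2
  rate: 0.1
  scaling_tag: none
- id: q07
  reactants:
    DiPhoBpp: 1
    pPhoA: 1
  products:
    pPhoAa: 1
  rate: 1.8
  scaling_tag: bf
- id: q08
  reactants:
    pPhoAa: 1
  products:
    DiPhoBpp: 1
    pPhoA: 1
  rate: 0.1
  scaling_tag: uf
- id: q09
  reactants:
    DiPhoBpp: 1
    pPhoB: 1
  products:
    pPhoBa: 1
  rate: 1.8
  scaling_tag: bf
- id: q10
  reactants:
    pPhoBa: 1
  products:
    DiPhoBpp: 1
    pPhoB: 1
  rate: 0.1
  scaling_tag: uf
- id: q11
  reactants:
    pPhoAa: 1
  products:
    pPhoAa: 1
    PhoA: 1
  rate: 0.08
  scaling_tag: none
- id: q12
  reactants:
    pPhoBa: 1
  products:
    pPhoBa: 1
    PhoB: 1
  rate: 0.4
  scaling_tag: none
- id: q13
  reactants:
    pPhoBa: 1
  products:
    pPhoBa: 1
    PhoR: 1
  rate: 0.08
  scaling_tag: none
- id: q14
  reactants:
    PhoA: 1
  products: {}
  rate: 0.0003
  scaling_tag: none
- id: q15
  reactants:
    PhoB: 1
  products: {}
  rate: 0.0003
  scaling_tag: none
- id: q16
  reactants:
    PhoR: 1
  products: {}
  rate: 0.0003
  scaling_tag: none
conservation_laws:
- species:
  - pPhoA
  - pPhoAa
  total_copies: 10
- species:
  - pPhoB
  - pPhoBa
  total_copies: 10
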