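model_id: phobr_full
volume_um3: 1.0
species:
- name: DiPhoR
  initial_concentration_uM: 1.0
  initial_copies: 602
- name: DiPhoRp
  initial_concentration_uM: 0.0
  initial_copies: 0
- name: DiPhoRpp
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
- name: C_RppB
  initial_concentration_uM: 0.0
  initial_copies: 0
- name: C_RpB
  initial_concentration_uM: 0.0
  initial_copies: 0
- name: C_RB
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
- name: mRNAa
  initial_concentration_uM: 0.0
  initial_copies: 0
- name: mRNAb
  initial_concentration_uM: 0.0
  initial_copies: 0
- name: PhoA
  initial_concentration_uM: 0.0
  initial_copies: 0
reactions:
- id: r01
  reactants:
    DiPhoR: 1
  products:
    DiPhoRp: 1
  rate: 0.05
  scaling_tag: fc
- id: r02
  reactants:
    DiPhoRp: 1
  products:
    DiPhoR: 1
  rate: 0.01
  scaling_tag: none
- id: r03
  reactants:
    DiPhoRp: 1
  products:
    DiPhoRpp: 1
  rate: 0.035
  scaling_tag: fc
- id: r04
  reactants:
    DiPhoRpp: 1
  products:
    DiPhoRp: 1
  rate: 0.01
  scaling_tag: none
- id: r05
  reactants:
    DiPhoRpp: 1
    PhoB: 1
  products:
    C_RppB: 1
  rate: 0.1
  scaling_tag: none
- id: r06
  reactants:
    C_RppB: 1
  products:
    DiPhoRpp: 1
    PhoB: 1
  rate: 0.5
  scaling_tag: none
- id: r07
  reactants:
    C_RppB: 1
  products:
    DiPhoRp: 1
    PhoBp: 1
  rate: 1.0
  scaling_tag: none
- id: r08
  reactants:
    DiPhoRp: 1
    PhoB: 1
  products:
    C_RpB: 1
  rate: 0.1
  scaling_tag: none
- id: r09
  reactants:
    C_RpB: 1
  products:
    DiPhoRp: 1
    PhoB: 1
  rate: 0.5
  scaling_tag: none
- id: r10
  reactants:
    C_RpB: 1
  products:
    DiPhoR: 1
    PhoBp: 1
  rate: 1.0
  scaling_tag: none
- id: r11
  reactants:
    PhoBp: 2
  products:
    DiPhoBpp: 1
  rate: 0.2
  scaling_tag: none
- id: r12
  reactants:
    DiPhoBpp: 1
  products:
    PhoBp: 2
  rate: 0.1
  scaling_tag: none
- id: r13
  reactants:
    DiPhoR: 1
    PhoBp: 1
  products:
    C_RB: 1
  rate: 0.05
  scaling_tag: none
- id: r14
  reactants:
    C_RB: 1
  products:
    DiPhoR: 1
    PhoBp: 1
  rate: 0.5
  scaling_tag: none
- id: r15
  reactants:
    C_RB: 1
  products:
    DiPhoR: 1
    PhoB: 1
  rate: 1.0
  scaling_tag: none
- id: r16
  reactants:
    DiPhoBpp: 1
    pPhoA: 1
  products:
    pPhoAa: 1
  rate: 1.8
  scaling_tag: bf
- id: r17
  reactants:
    pPhoAa: 1
  products:
    DiPhoBpp: 1
    pPhoA: 1
  rate: 0.1
  scaling_tag: uf
- id: r18
  reactants:
    DiPhoBpp: 1
    pPhoB: 1
  products:
    pPhoBa: 1
  rate: 1.8
  scaling_tag: bf
- id: r19
  reactants:
    pPhoBa: 1
  products:
    DiPhoBpp: 1
    pPhoB: 1
  rate: 0.1
  scaling_tag: uf
- id: r20
  reactants:
    pPhoAa: 1
  products:
    pPhoAa: 1
    mRNAa: 1
  rate: 0.03
  scaling_tag: none
- id: r21
  reactants:
    pPhoBa: 1
  products:
    pPhoBa: 1
    mRNAb: 1
  rate: 0.01
  scaling_tag: none
- id: r22
  reactants:
    mRNAa: 1
  products:
    mRNAa: 1
    PhoA: 1
  rate: 0.08
  scaling_tag: none
- id: r23
  reactants:
    mRNAb: 1
  products:
    mRNAb: 1
    PhoB: 1
  rate: 0.2
  scaling_tag: none
- id: r24
  reactants:
    mRNAb: 1
  products:
    mRNAb: 1
    DiPhoR: 1
  rate: 0.04
  scaling_tag: none
- id: r25
  reactants:
    mRNAa: 1
  products: {}
  rate: 0.03
  scaling_tag: none
- id: r26
  reactants:
    mRNAb: 1
  products: {}
  rate: 0.005
  scaling_tag: none
- id: r27
  reactants:
    PhoA: 1
  products: {}
  rate: 0.0003
  scaling_tag: none
- id: r28
  reactants:
    PhoB: 1
  products: {}
  rate: 0.0003
  scaling_tag: none
- id: r29
  reactants:
    DiPhoR: 1
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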