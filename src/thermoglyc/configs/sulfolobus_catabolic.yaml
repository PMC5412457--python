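name: sulfolobus_catabolic
organism: sulfolobus
temperature_C: 70.0
species:
- name: GAP
  initial_mM: 0.15
  boundary: true
- name: NADP
  initial_mM: 1.2
  boundary: true
- name: NADPH
  initial_mM: 0.39
  boundary: true
- name: Pi
  initial_mM: 10.0
  boundary: true
- name: PYR
  initial_mM: 0.0
  boundary: true
- name: ATP
  initial_mM: 2.52
  boundary: true
- name: ADP
  initial_mM: 1.32
  boundary: true
- name: BPG
  initial_mM: 0.0
  boundary: false
- name: 3PG
  initial_mM: 0.0
  boundary: false
- name: 2PG
  initial_mM: 0.0
  boundary: false
- name: PEP
  initial_mM: 0.0
  boundary: false
reactions:
- name: GAPDH
  rate_law: GAPDH_ssol
  stoichiometry:
    GAP: -1
    NADP: -1
    Pi: -1
    BPG: 1
    NADPH: 1
  parameters:
    Vm: 66.0
    KmGAP: 3.1
    KmNADP: 0.2
    KmNADPH: 0.094
    KmBPG: 0.089
    KmPi: 108.52
    Keq: 0.0001852591774292476
- name: PGK
  rate_law: PGK_shared
  stoichiometry:
    BPG: -1
    ADP: -1
    3PG: 1
    ATP: 1
  parameters:
    Vmr: 73.0
    KmADP: 0.374
    KmATP: 9.303
    KmBPG: 0.008
    Km3PG: 0.567
    KiADP: 1.14
    Keq: 3793.0
- name: PGMA
  rate_law: PGMA
  stoichiometry:
    3PG: -1
    2PG: 1
  parameters:
    Km3PG: 1.2
    Km2PG: 0.08
    Keq: 0.19
    Vm: 56.0
- name: ENO
  rate_law: ENO
  stoichiometry:
    2PG: -1
    PEP: 1
  parameters:
    Km2PG: 0.04
    KmPEP: 0.5
    Keq: 6.7
    Vm: 20.5
- name: PYK
  rate_law: PYK
  stoichiometry:
    PEP: -1
    ADP: -1
    PYR: 1
    ATP: 1
  parameters:
    KmADP: 0.53
    KmATP: 1.5
    KmPEP: 0.14
    KmPYR: 21.0
    Keq: 6500.0
    Vm: 76.0
- name: BPG_degradation
  rate_law: BPG_degradation
  stoichiometry:
    BPG: -1
    3PG: 1
  parameters:
    KdBPG: 1.058
- name: GAPN
  rate_law: GAPN
  stoichiometry:
    GAP: -1
    NADP: -1
    3PG: 1
    NADPH: 1
  parameters:
    Vm: 20.0
    KmGAP: 0.02
    KmNADP: 0.09
moieties: []
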