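name: yeast_base
organism: yeast
temperature_C: 30.0
species:
- name: GAP
  initial_mM: 0.15
  boundary: true
- name: NAD
  initial_mM: 1.2
  boundary: true
- name: NADH
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
  rate_law: GAPDH_yeast
  stoichiometry:
    GAP: -1
    NAD: -1
    Pi: -1
    BPG: 1
    NADH: 1
  parameters:
    Vm: 1859.0
    KmGAP: 0.21
    KmNAD: 0.09
    KmNADH: 0.06
    KmBPG: 0.0098
    KmPi: 1.5
    Keq: 0.0054
- name: PGK
  rate_law: PGK_shared
  stoichiometry:
    BPG: -1
    ADP: -1
    3PG: 1
    ATP: 1
  parameters:
    Vmr: 2670.0
    KmADP: 0.2
    KmATP: 0.3
    KmBPG: 0.003
    Km3PG: 0.53
    KiADP: inf
    Keq: 3200.0
- name: PGMA
  rate_law: PGMA
  stoichiometry:
    3PG: -1
    2PG: 1
  parameters:
    Km3PG: 1.2
    Km2PG: 0.08
    Keq: 0.19
    Vm: 856.0
- name: ENO
  rate_law: ENO
  stoichiometry:
    2PG: -1
    PEP: 1
  parameters:
    Km2PG: 0.04
    KmPEP: 0.5
    Keq: 6.7
    Vm: 357.0
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
    Vm: 559.0
moieties: []
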