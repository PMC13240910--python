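disorder:
  scale:
    A: 0.06
    C: 0.02
    D: 0.192
    E: 0.736
    F: -0.697
    G: 0.166
    H: 0.303
    I: -0.486
    K: 0.586
    L: -0.326
    M: -0.397
    N: 0.007
    P: 0.987
    Q: 0.318
    R: 0.18
    S: 0.341
    T: 0.059
    V: -0.121
    W: -0.884
    Y: -0.51
  threshold: 0.0
groups:
  hydrophobic:
  - A
  - F
  - I
  - L
  - M
  - V
  - W
  - Y
  negative:
  - D
  - E
  polar:
  - N
  - Q
  - S
  - T
  positive:
  - H
  - K
  - R
  sulfur:
  - C
  - M
  tiny:
  - A
  - G
  - S
  - T
hydropathy:
  A: 1.8
  C: 2.5
  D: -3.5
  E: -3.5
  F: 2.8
  G: -0.4
  H: -3.2
  I: 4.5
  K: -3.9
  L: 3.8
  M: 1.9
  N: -3.5
  P: -1.6
  Q: -3.5
  R: -4.5
  S: -0.8
  T: -0.7
  V: 4.2
  W: -0.9
  Y: -1.3
masses:
  A: 71.0788
  C: 103.1388
  D: 115.0886
  E: 129.1155
  F: 147.1766
  G: 57.0519
  H: 137.1411
  I: 113.1594
  K: 128.1741
  L: 113.1594
  M: 131.1926
  N: 114.1038
  P: 97.1167
  Q: 128.1307
  R: 156.1875
  S: 87.0782
  T: 101.1051
  V: 99.1326
  W: 186.2132
  Y: 163.176
pka:
  C: 8.5
  D: 3.9
  E: 4.1
  H: 6.5
  K: 10.8
  R: 12.5
  Y: 10.1
  c_term: 3.6
  n_term: 8.6
propensities:
  helix:
    A: 1.42
    C: 0.7
    D: 1.01
    E: 1.51
    F: 1.13
    G: 0.57
    H: 1.0
    I: 1.08
    K: 1.16
    L: 1.21
    M: 1.45
    N: 0.67
    P: 0.57
    Q: 1.11
    R: 0.98
    S: 0.77
    T: 0.83
    V: 1.06
    W: 1.08
    Y: 0.69
  sheet:
    A: 0.83
    C: 1.19
    D: 0.54
    E: 0.37
    F: 1.38
    G: 0.75
    H: 0.87
    I: 1.6
    K: 0.74
    L: 1.3
    M: 1.05
    N: 0.89
    P: 0.55
    Q: 1.1
    R: 0.93
    S: 0.75
    T: 1.19
    V: 1.7
    W: 1.37
    Y: 1.47
  turn:
    A: 0.66
    C: 1.19
    D: 1.46
    E: 0.74
    F: 0.6
    G: 1.56
    H: 0.95
    I: 0.47
    K: 1.01
    L: 0.59
    M: 0.6
    N: 1.56
    P: 1.52
    Q: 0.98
    R: 0.95
    S: 1.43
    T: 0.96
    V: 0.5
    W: 0.96
    Y: 1.14
provenance:
  disorder: TOP-IDP (Campen et al., 2008), tau=0.0
  groups: charge/polarity/hydrophobicity/size/sulfur residue groups
  hydropathy: Kyte & Doolittle (1982)
  masses: Expasy average residue masses
  pka: EMBOSS side-chain and termini pKa set
  propensities: Chou & Fasman (1978)
water_mass: 18.01524
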