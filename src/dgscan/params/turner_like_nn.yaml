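# Nearest-neighbor free-energy parameters at 37 C, kcal/mol.
#
# Stack keys read "XY>ZW": outer pair X(5')-Y(3') stacked on the adjacent
# inner pair Z-W, i.e. 5'-X Z ... W Y-3'.  The table is symmetric under
# reading the helix from the other strand: XY>ZW == WZ>YX (checked on load).
#
# Loop initiation penalties are indexed by the number of unpaired residues
# in the loop (hairpin >= 3, bulge >= 1, internal >= 2, size-only, no
# asymmetry term).  Sizes beyond the table are extrapolated as
#   E(n) = E(n_max) + loop_extrapolation_coeff * ln(n / n_max)
# with coefficient 1.75 * R * T at 310.15 K.
#
# Multiloops use an affine model: offset + per_branch * (branches incl. the
# closing pair) + per_unpaired * (unpaired residues inside the loop).
stacks:
  AU>AU: -0.93
  AU>UA: -1.10
  AU>CG: -2.24
  AU>GC: -2.08
  AU>GU: -0.55
  AU>UG: -1.36
  UA>AU: -1.33
  UA>UA: -0.93
  UA>CG: -2.35
  UA>GC: -2.11
  UA>GU: -1.00
  UA>UG: -1.27
  CG>AU: -2.11
  CG>UA: -2.08
  CG>CG: -3.26
  CG>GC: -2.36
  CG>GU: -1.41
  CG>UG: -2.11
  GC>AU: -2.35
  GC>UA: -2.24
  GC>CG: -3.42
  GC>GC: -3.26
  GC>GU: -1.53
  GC>UG: -2.51
  GU>AU: -1.27
  GU>UA: -1.36
  GU>CG: -2.51
  GU>GC: -2.11
  GU>GU: -0.50
  GU>UG: -0.30
  UG>AU: -1.00
  UG>UA: -0.55
  UG>CG: -1.53
  UG>GC: -1.41
  UG>GU: -0.30
  UG>UG: -0.50
hairpin:
  3: 5.4
  4: 5.6
  5: 5.7
  6: 5.4
  7: 6.0
  8: 5.5
  9: 6.4
bulge:
  1: 3.8
  2: 2.8
  3: 3.2
  4: 3.6
  5: 4.0
  6: 4.4
internal:
  2: 1.5
  3: 1.6
  4: 1.7
  5: 1.8
  6: 2.0
  7: 2.2
  8: 2.3
  9: 2.4
  10: 2.5
multiloop:
  offset: 3.4
  per_branch: 0.4
  per_unpaired: 0.1
loop_extrapolation_coeff: 1.0785
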