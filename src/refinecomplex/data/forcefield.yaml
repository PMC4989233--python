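# Simplified per-element Lennard-Jones parameters (radius = Rmin/2 in
# Angstrom, epsilon in kcal/mol) and per-residue partial charges (e).
# Atoms not listed under `charges` default to the backbone values or 0.
elements:
  C: {radius: 1.95, epsilon: 0.07}
  N: {radius: 1.85, epsilon: 0.17}
  O: {radius: 1.75, epsilon: 0.15}
  S: {radius: 2.00, epsilon: 0.45}
backbone_charges: {N: -0.40, CA: 0.40, C: 0.45, O: -0.45}
charges:
  SER: {CB: 0.40, OG: -0.40}
  THR: {CB: 0.40, OG1: -0.40}
  CYS: {CB: 0.15, SG: -0.15}
  TYR: {CZ: 0.40, OH: -0.40}
  MET: {CG: 0.05, SD: -0.10, CE: 0.05}
  ASP: {CG: 0.30, OD1: -0.65, OD2: -0.65}
  GLU: {CD: 0.30, OE1: -0.65, OE2: -0.65}
  ASN: {CB: 0.30, CG: 0.55, OD1: -0.55, ND2: -0.30}
  GLN: {CG: 0.30, CD: 0.55, OE1: -0.55, NE2: -0.30}
  LYS: {CE: 0.35, NZ: 0.65}
  ARG: {NE: -0.10, CZ: 0.50, NH1: 0.30, NH2: 0.30}
  HIS: {CG: 0.10, ND1: -0.36, CD2: 0.10, CE1: 0.32, NE2: -0.16}
  TRP: {CD1: 0.15, NE1: -0.35, CE2: 0.20}
# bonded force constants (deliberately stiffness-capped for a 4 fs timestep)
k_bond: 100.0      # kcal/mol/A^2
k_angle: 25.0      # kcal/mol/rad^2
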