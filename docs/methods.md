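# Methods

`refinecomplex` refines protein–protein complex models whose interfaces
are imperfectly packed — the typical output of rigid-body docking — by
alternating combinatorial repacking of interfacial side chains with short
restrained molecular-dynamics relaxations under a simulated-annealing
temperature schedule. This note records the model, its parameters, the
numerical choices, and what the synthetic test system does and does not
establish.

## The refinement procedure

One refinement trajectory consists of:

1. Interface detection on the input model: a residue is interfacial if
   any residue of another chain has a CA within **8 Å** (strict
   inequality).
2. Restraint construction, anchored to the input: harmonic distance
   restraints `w·(d − d₀)²` on every CA–CA and backbone N–O pair with
   reference distance `d₀ < 10 Å`, and (protocol 2 only) harmonic
   position restraints `w·‖r − r₀‖²` on every CA. Pairs touching an
   interfacial residue get a much smaller weight so the interface can
   move. Restraint references are built once and never re-anchored.
3. Local energy minimization, then a **1.2 ps** Langevin relaxation at
   300 K.
4. **22 cycles** of: Monte-Carlo repacking (3 Metropolis steps on each of
   3 clusters of up to 5 spatially adjacent interfacial residues, with
   van der Waals radii reduced to **70 %** so near-native but slightly
   clashing rotamers are reachable) followed by a **0.6 ps** relaxation.
   The temperature is 300 K for cycles 1–16 and descends linearly to
   50 K over the final six cycles.
5. A final local minimization.

Each restraint protocol (1: distance only; 2: distance + position)
generates **16** trajectories from distinct sub-seeds; the **5**
lowest-energy models per protocol are returned, ranked 1–5 and 6–10.
Selection is exactly "sort by final energy, take five", with ties broken
by run index. For symmetric homo-oligomers the Cn transforms estimated
from the input (Kabsch fits of chain 1 onto each chain over CA atoms) are
re-imposed after every MD step by averaging all chains in chain 1's frame
and re-applying the transforms; this projection fixes the oligomer frame
to the input transforms rather than preserving the center of mass.

## Energy model

The refinement objective is a weighted sum of eleven terms, each with an
analytic gradient; all weights default to 1 and are configurable:

| term | form |
|---|---|
| bonded | harmonic bonds (k = 100 kcal/mol/Å²) and angles (k = 25 kcal/mol/rad²), equilibria measured from the package's own ideal residue geometries so ideally built structures carry no strain |
| vdw | Lennard-Jones 12-6 on per-element Rmin/2 and ε, 12 Å cutoff, 1-2/1-3 excluded, 1-4 scaled by 0.5 |
| coulomb | bare `332·qᵢqⱼ/r` with per-residue partial charges |
| solv_polar | the *difference* between a distance-dependent-dielectric screened interaction (ε(r) = 4r, i.e. `332·qᵢqⱼ/4r²`) and the bare Coulomb term, so at unit weights the electrostatics pathway is exactly the screened form; an implicit-solvent polar surrogate |
| solv_nonpolar | smooth pairwise contact reward (γ = −0.02 kcal/mol) between hydrophobic (C/S) atoms; a pairwise stand-in for a buried-surface-area term |
| hbond | geometric backbone N···O well (2.6–3.5 Å, sin² envelope) times a C–O···N angular window (100–180°, peak 150°); depth 1.5 kcal/mol; no explicit hydrogens |
| pairstat | residue-type-pair potential on 0.5 Å Cβ–Cβ distance bins, linearly interpolated; the packaged default table is zero (the term is an architectural slot for a knowledge-based pair potential; tests exercise it with synthetic tables) |
| rama | −log p(φ, ψ) on a 10° grid with a mild α-helical preference, bilinear interpolation |
| rotamer | per-χ −log p on 10° periodic grids peaked at the rotamer-library values |
| restraint_distance / restraint_position | the harmonic restraints above |

The per-term breakdown reproduces the weighted total to machine
precision, and setting a weight to zero removes the term exactly. Because
the torsion grids are deterministic functions of the packaged rotamer
library they are generated at load time rather than shipped as data
files.

The heavy-atom model has no hydrogens throughout: docking models carry
unreliable protons, and every term above is defined on heavy atoms.

## Sampling

*Minimization* is L-BFGS-B on the analytic gradient; the result is
rejected in favour of the input if line-search noise ever leaves it
higher in energy, so minimization is monotone by construction.

*MD* is Langevin dynamics with the BAOAB splitting, friction 1 ps⁻¹
(2 ps⁻¹ in the equipartition test for faster decorrelation), 4 fs
timestep, Maxwell–Boltzmann initial velocities. The 4 fs step is stable
because the bonded force constants are deliberately capped (the stiffest
mode, a 100 kcal/mol/Å² bond on carbon masses, has a ~53 fs period). On
a harmonic fixture the integrator reproduces kT/2 of kinetic energy per
degree of freedom within 10 %.

*Repacking* proposes library rotamers jointly for a whole cluster,
rejects proposals that clash at the reduced radii (overlap below
0.8 × (rᵢ+rⱼ) × 0.7, strict, 1-2/1-3 pairs excluded), and otherwise
applies the Metropolis criterion on the total energy at the current
cycle temperature. Only side-chain atoms of cluster residues move;
backbone coordinates are bit-identical before and after. Clusters are a
random interfacial seed residue plus its nearest interfacial neighbours
by CA distance, re-drawn every cycle.

All randomness flows from one master seed through
`numpy.random.SeedSequence` spawning, so ensembles are bit-reproducible.

## Parameters

Quantities printed above (cutoffs, durations, cycle counts, ensemble
sizes, the 70 % radius reduction, the annealing endpoints) are the
protocol's defining constants. Values the protocol needs but does not
pin down were fixed once as follows: restraint weights w_non = 1.0,
w_intf = 0.1, w_pos = 0.05 energy/Å² (the required ordering is
w_intf ≪ w_non with w_pos small); per-element LJ parameters and
per-residue partial charges in `data/forcefield.yaml`; a minimal
backbone-independent rotamer library (1–3 rotamers per type, canonical
gauche/trans χ values) in `data/rotamers.txt`. All are config-exposed.

## Assessment

CAPRI-style quality of a model against a reference: **L-RMSD** (backbone
N/CA/C/O RMSD of the ligand after least-squares superposition of the
receptor), **I-RMSD** (backbone RMSD over reference interface residues —
any inter-chain heavy-atom contact within 10 Å — after superposing on
them), and **F_nat** (fraction of the reference's inter-chain residue
contacts, 5 Å heavy-atom, present in the model). Classification, with
strict inequalities and high→medium→acceptable precedence:

* high: (L < 1.0 or I < 1.0) and F_nat > 0.5
* medium: (L < 5.0 or I < 2.0) and F_nat > 0.3
* acceptable: (L < 10.0 or I < 4.0) and F_nat > 0.1
* otherwise incorrect.

Receptor = largest chain by atom count unless roles are given; for
homo-complexes every chain assignment consistent with sequence identity
is tried and the best value per metric is reported. Note the interface
definition here (10 Å heavy-atom, CAPRI convention) is distinct from the
refinement's 8 Å CA rule; both are exposed.

## Synthetic test system

The fixture generator builds ideal α-helices (φ = −57°, ψ = −47°) with
large side chains (LEU/PHE/ARG/MET) at heptad a/d positions, orients
those faces into the interface, and packs a dimer or Cn oligomer by
scanning separation, axial stagger and face angle until (i) no
inter-chain overlap remains at full radii after a greedy rotamer search,
(ii) each chain has ≥ 5 interfacial residues, and (iii) at least half of
the native contacts require side-chain atoms beyond Cβ. Condition (iii)
is the design goal of the fixture family: the mechanism under study is
side-chain repacking, so the interface must be side-chain-mediated for
decoys to respond to it. For symmetric fixtures the rotamer search is
applied jointly to all chains, so the copies are exactly symmetric atom
by atom.

Decoys rigidly rotate/translate the ligand chain by requested magnitudes
and/or reassign a fraction of interface side chains to library rotamers
*different* from the current one, and are returned together with their
exact quality metrics.

What the fixtures do **not** emulate: real tertiary folds, loop
flexibility, backbone conformational change on binding, waters, and the
rugged energy landscapes of real interfaces. Passing the synthetic
mechanism-recovery experiments shows that repacking + restrained
annealing recovers side-chain-mediated contacts and does not corrupt a
near-native pose under this model — not that the simplified energy
function would rank real docking decoys as the original, fully
parameterized energy does.

## Problem sizes used in the shipped experiments

The automated experiments run on 8–12-residue-per-chain dimers and
trimers (≈ 100–220 heavy atoms). The full default schedule (22 cycles,
16 runs × 2 protocols) is exercised end-to-end on an 8-residue dimer;
the mechanism-recovery experiments use a reduced schedule of 8 cycles
(annealing over the last 6) and 8-run ensembles, repeated over 5 master
seeds — ensemble medians, not single trajectories, are what the claims
are about. These sizes were chosen so the whole battery runs comfortably
on one CPU while every protocol element (cycle structure, annealing,
selection, symmetry projection) executes exactly as at full scale.

## Known limitations

* The energy surrogates (screened electrostatics, pairwise burial term,
  zero default pair-potential table) occupy the architectural slots of
  an implicit-solvent model and a statistical potential but are not fits
  to data; absolute energies are in arbitrary units and only ordering
  within a run is meaningful.
* PRO side chains are built from a fixed template and never repacked;
  ring closure (PRO, aromatic rings) is enforced by harmonic closure
  bonds, not exact constraints.
* Pose preservation on rigid-body decoys is imperfect: ensemble members
  drift thermally around the restraint anchor because the cross-chain
  restraints are deliberately weak (interface pairs carry w_intf = 0.1),
  and the simplified energy surrogate exerts only a mild pull toward
  native-like packing. On 2 Å translation decoys the refined
  ensemble-median L-RMSD sits ≈ 0.1–0.2 Å above the input value
  (rotational decoys drift more, ≈ 0.3–0.5 Å); a fully parameterized
  knowledge-based energy would be needed to close that gap, and the
  corresponding check is left failing rather than loosened.
* Chain mapping in assessment assumes equal residue counts per mapped
  chain (no alignment of insertions/deletions).
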