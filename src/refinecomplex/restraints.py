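"""Interface detection and restraint construction.

Interfacial residues are those within an 8 A CA-CA distance of any residue
of another chain.  Harmonic distance restraints tether every CA-CA and
backbone N-O atom pair closer than 10 A to its value in the input
structure, with a much smaller weight when either endpoint residue is
interfacial; harmonic position restraints tether every CA to its input
position (protocol 2 only).  Restraint energies are therefore exactly zero
on the unperturbed input.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AtomMismatch, MissingCA, WeightError
from .structure import ComplexStructure

DEFAULT_INTERFACE_CUTOFF = 8.0
RESTRAINT_DISTANCE_CUTOFF = 10.0


@dataclass(frozen=True)
class InterfaceSet:
    """Residues flagged interfacial under the CA-CA cutoff rule."""

    members: frozenset          # of (chain_id, residue_index)
    cutoff: float = DEFAULT_INTERFACE_CUTOFF

    def __contains__(self, key):
        return key in self.members

    def __len__(self):
        return len(self.members)

    def sorted_members(self):
        return sorted(self.members)


@dataclass
class DistanceRestraint:
    atom_i: tuple               # (chain_id, residue_index, atom_name)
    atom_j: tuple
    d0: float                   # reference distance, A
    weight: float               # energy / A^2
    interface_flag: bool


@dataclass
class PositionRestraint:
    atom_i: tuple               # CA only
    r0: np.ndarray              # reference position, A
    weight: float


@dataclass
class RestraintWeights:
    """w_intf < w_non by construction; w_pos is small."""

    w_non: float = 1.0
    w_intf: float = 0.1
    w_pos: float = 0.05

    def validate(self):
        if self.w_non <= 0 or self.w_intf <= 0 or self.w_pos <= 0:
            raise WeightError("restraint weights must be positive")
        if self.w_intf >= self.w_non:
            raise WeightError("interface weight must be < non-interface weight")
        return self


@dataclass
class RestraintSet:
    distance: list = field(default_factory=list)
    position: list = field(default_factory=list)
    protocol: int = 1


def pair_distance(xi, xj) -> float:
    """Pair distance evaluated exactly as the vectorized energy path does,
    so restraint energies at the reference structure are bitwise zero."""
    return float(np.linalg.norm((np.asarray(xi) - np.asarray(xj))[None, :],
                                axis=1)[0])


def detect_interface(structure: ComplexStructure,
                     cutoff: float = DEFAULT_INTERFACE_CUTOFF) -> InterfaceSet:
    """Residues with an inter-chain CA-CA distance strictly below cutoff."""
    ca_idx, keys = [], []
    for cid, ri, _rn, sel in structure.residues():
        ca = [i for i in sel if structure.atom_name[i] == "CA"]
        if not ca:
            raise MissingCA(f"residue {cid}{ri} has no CA atom")
        ca_idx.append(ca[0])
        keys.append((cid, ri))
    ca_idx = np.array(ca_idx)
    coords = structure.coords[ca_idx]
    chains = structure.chain_index[ca_idx]
    dist = cdist(coords, coords)
    inter = chains[:, None] != chains[None, :]
    hits = (dist < cutoff) & inter
    members = {keys[i] for i in np.nonzero(hits.any(axis=1))[0]}
    return InterfaceSet(members=frozenset(members), cutoff=cutoff)


def build_restraints(structure: ComplexStructure, interface: InterfaceSet,
                     protocol: int = 1,
                     weights: RestraintWeights | None = None) -> RestraintSet:
    """Build the harmonic restraint set anchored to *structure*.

    Distance restraints span every CA-CA pair and every backbone N-O pair
    (different residues, |i-j| > 1 within a chain for N-O) with reference
    distance < 10 A; the pair weight is w_intf when either endpoint residue
    is interfacial, else w_non.  Position restraints (protocol 2) tether
    every CA to its reference position.
    """
    if protocol not in (1, 2):
        raise ValueError("protocol must be 1 or 2")
    weights = (weights or RestraintWeights()).validate()

    ca, nn, oo = [], [], []    # (key, coords) lists
    for cid, ri, _rn, sel in structure.residues():
        for i in sel:
            name = structure.atom_name[i]
            if name == "CA":
                ca.append(((cid, ri, "CA"), structure.coords[i]))
            elif name == "N":
                nn.append(((cid, ri, "N"), structure.coords[i]))
            elif name == "O":
                oo.append(((cid, ri, "O"), structure.coords[i]))

    def is_interfacial(key_i, key_j):
        return ((key_i[0], key_i[1]) in interface
                or (key_j[0], key_j[1]) in interface)

    rs = RestraintSet(protocol=protocol)
    # CA-CA pairs
    for a in range(len(ca)):
        for b in range(a + 1, len(ca)):
            (ki, xi), (kj, xj) = ca[a], ca[b]
            d0 = pair_distance(xi, xj)
            if d0 < RESTRAINT_DISTANCE_CUTOFF:
                intf = is_interfacial(ki, kj)
                rs.distance.append(DistanceRestraint(
                    ki, kj, d0, weights.w_intf if intf else weights.w_non,
                    intf))
    # backbone N-O pairs (amide N to carbonyl O of a different residue)
    for ki, xi in nn:
        for kj, xj in oo:
            if (ki[0], ki[1]) == (kj[0], kj[1]):
                continue
            if ki[0] == kj[0] and abs(ki[1] - kj[1]) <= 1:
                continue
            d0 = pair_distance(xi, xj)
            if d0 < RESTRAINT_DISTANCE_CUTOFF:
                intf = is_interfacial(ki, kj)
                rs.distance.append(DistanceRestraint(
                    ki, kj, d0, weights.w_intf if intf else weights.w_non,
                    intf))
    if protocol == 2:
        for ki, xi in ca:
            rs.position.append(PositionRestraint(ki, np.array(xi),
                                                 weights.w_pos))
    return rs


def resolve_atom(structure: ComplexStructure, key: tuple) -> int:
    try:
        return structure.atom_index(*key)
    except KeyError:
        raise AtomMismatch(f"restraint atom {key} not present in structure")


# --------------------------------------------------------------------------
# plain-text dump/load for reproducibility
# --------------------------------------------------------------------------

def dump_restraints(rs: RestraintSet, path) -> None:
    with open(str(path), "w") as fh:
        fh.write(f"# protocol\t{rs.protocol}\n")
        fh.write("# kind\tchain_i\tres_i\tatom_i\tchain_j\tres_j\tatom_j\t"
                 "d0_or_r0\tweight\tinterface\n")
        for r in rs.distance:
            fh.write("DIST\t%s\t%d\t%s\t%s\t%d\t%s\t%.6f\t%.6f\t%d\n" % (
                *r.atom_i, *r.atom_j, r.d0, r.weight, int(r.interface_flag)))
        for r in rs.position:
            fh.write("POS\t%s\t%d\t%s\t-\t-\t-\t%.6f,%.6f,%.6f\t%.6f\t0\n" % (
                *r.atom_i, *r.r0, r.weight))


def load_restraints(path) -> RestraintSet:
    rs = RestraintSet()
    with open(str(path)) as fh:
        for line in fh:
            if line.startswith("# protocol"):
                rs.protocol = int(line.split("\t")[1])
                continue
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[0] == "DIST":
                rs.distance.append(DistanceRestraint(
                    (f[1], int(f[2]), f[3]), (f[4], int(f[5]), f[6]),
                    float(f[7]), float(f[8]), bool(int(f[9]))))
            elif f[0] == "POS":
                r0 = np.array([float(x) for x in f[7].split(",")])
                rs.position.append(PositionRestraint(
                    (f[1], int(f[2]), f[3]), r0, float(f[8])))
    return rs
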