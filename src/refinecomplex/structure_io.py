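"""PDB input/output and homo-oligomer symmetry operations.

Reading and writing go through gemmi; only standard amino-acid ATOM
records are kept (hydrogens dropped, altlocs resolved to blank/"A",
HETATM and non-standard residues skipped with a warning).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from . import chemistry as chem
from .errors import (ChainCountError, DegenerateGeometry, GroupMismatch,
                     IncompleteBackbone, MalformedPDB, SequenceMismatch)
from .structure import ComplexStructure, from_residue_dicts

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# rigid superposition (used here and by assessment)
# --------------------------------------------------------------------------

def kabsch_fit(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid transform (R, t) minimizing |R @ x + t - y|.

    Returns (R, t, rmsd).  Wraps scipy's quaternion-based solver.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise DegenerateGeometry("need >= 3 paired points for superposition")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    t = tc - R @ mc
    rmsd = rssd / np.sqrt(mobile.shape[0])
    return R, t, float(rmsd)


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray):
    return coords @ R.T + t


# --------------------------------------------------------------------------
# PDB reading / writing
# --------------------------------------------------------------------------

def read_pdb(path, mode: str = "heteromer") -> ComplexStructure:
    """Read a protein complex model from a PDB file.

    mode="symmetric" additionally requires all chains to share one sequence.
    """
    if mode not in ("heteromer", "symmetric"):
        raise ValueError("mode must be 'heteromer' or 'symmetric'")
    import os
    if not os.path.exists(str(path)):
        raise FileNotFoundError(2, "no such file", str(path))
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MalformedPDB(str(exc)) from exc
    if len(st) == 0:
        raise MalformedPDB(f"no models in {path}")
    model = st[0]
    residues = []
    for chain in model:
        for res in chain:
            if res.het_flag != "A" or res.name not in chem.AA3:
                log.warning("skipping non-standard residue %s %s%s",
                            res.name, chain.name, res.seqid.num)
                continue
            atom_map = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                if atom.altloc not in ("\0", "", "A"):
                    continue
                if atom.name in atom_map:
                    continue
                atom_map[atom.name] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z])
            known = set(chem.residue_atom_names(res.name))
            atom_map = {k: v for k, v in atom_map.items() if k in known}
            if not atom_map:
                continue
            missing = set(chem.BACKBONE_ATOMS) - set(atom_map)
            if missing:
                raise IncompleteBackbone(
                    f"residue {res.name} {chain.name}{res.seqid.num} missing "
                    f"{sorted(missing)}")
            residues.append((chain.name, res.name, atom_map, res.seqid.num))
    structure = from_residue_dicts(residues, provenance=str(path))
    if structure.n_chains < 2:
        raise ChainCountError(
            f"{path}: found {structure.n_chains} protein chain(s), need >= 2")
    structure.validate()
    if mode == "symmetric":
        seqs = set(structure.sequences.values())
        if len(seqs) > 1:
            raise SequenceMismatch(
                "symmetric mode requires identical chain sequences")
    return structure


def write_pdb(structure: ComplexStructure, path) -> None:
    """Write standard ATOM records with TER between chains and a final END."""
    st = gemmi.Structure()
    st.name = "refinecomplex"
    model = gemmi.Model("1")
    for cid in structure.chain_ids:
        chain = gemmi.Chain(cid)
        for _cid, ri, rname, sel in structure.residues(cid):
            res = gemmi.Residue()
            res.name = rname
            res.seqid = gemmi.SeqId(int(structure.orig_resnum[sel[0]]), " ")
            res.het_flag = "A"
            for i in sel:
                atom = gemmi.Atom()
                atom.name = structure.atom_name[i]
                atom.element = gemmi.Element(structure.element[i])
                x, y, z = structure.coords[i]
                atom.pos = gemmi.Position(float(x), float(y), float(z))
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# --------------------------------------------------------------------------
# symmetry
# --------------------------------------------------------------------------

@dataclass
class SymmetryGroup:
    """Rigid transforms mapping chain 1 onto each chain of a Cn oligomer."""

    n_copies: int
    rotations: list = field(default_factory=list)     # 3x3 matrices
    translations: list = field(default_factory=list)  # 3-vectors
    fit_rmsd: list = field(default_factory=list)      # per-chain fit RMSD

    def transform(self, k: int):
        return self.rotations[k], self.translations[k]


def estimate_symmetry(structure: ComplexStructure) -> SymmetryGroup:
    """Least-squares transforms (Kabsch over CA atoms) chain 1 -> chain k."""
    seqs = list(structure.sequences.values())
    if len(set(seqs)) > 1:
        raise SequenceMismatch("all chains must share one sequence")
    ref_ca = structure.coords[structure.ca_indices(structure.chain_ids[0])]
    if ref_ca.shape[0] < 3:
        raise DegenerateGeometry("chain has fewer than 3 CA atoms")
    group = SymmetryGroup(n_copies=structure.n_chains)
    for k, cid in enumerate(structure.chain_ids):
        if k == 0:
            group.rotations.append(np.eye(3))
            group.translations.append(np.zeros(3))
            group.fit_rmsd.append(0.0)
            continue
        ca_k = structure.coords[structure.ca_indices(cid)]
        R, t, rmsd = kabsch_fit(ref_ca, ca_k)
        group.rotations.append(R)
        group.translations.append(t)
        group.fit_rmsd.append(rmsd)
    return group


def enforce_symmetry(structure: ComplexStructure,
                     group: SymmetryGroup) -> ComplexStructure:
    """Project the oligomer onto exact Cn symmetry.

    Every chain is mapped into chain 1's frame by the inverse transforms,
    the mapped copies are averaged into a consensus chain, and the
    transforms are re-applied.  Atom count and identities are unchanged.
    """
    if structure.n_chains != group.n_copies:
        raise GroupMismatch(
            f"structure has {structure.n_chains} chains, group expects "
            f"{group.n_copies}")
    per_chain = [structure.chain_atoms(cid) for cid in structure.chain_ids]
    n0 = len(per_chain[0])
    if any(len(sel) != n0 for sel in per_chain):
        raise GroupMismatch("chains differ in atom count")
    consensus = np.zeros((n0, 3))
    for k, sel in enumerate(per_chain):
        R, t = group.transform(k)
        consensus += (structure.coords[sel] - t) @ R  # inverse: R^T (x - t)
    consensus /= group.n_copies
    coords = structure.coords.copy()
    for k, sel in enumerate(per_chain):
        R, t = group.transform(k)
        coords[sel] = consensus @ R.T + t
    return structure.with_coords(coords, provenance=structure.provenance)
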