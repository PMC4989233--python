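"""In-memory representation of a protein complex model.

A :class:`ComplexStructure` stores heavy atoms of a multi-chain protein in
flat numpy arrays (struct-of-arrays), which the energy and sampling code
indexes directly.  Residues are re-indexed 1..N per chain internally; the
original author numbering is kept for output.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import chemistry as chem
from .errors import IncompleteBackbone, MalformedPDB


@dataclass
class AtomRecord:
    """One heavy atom (PDB naming conventions)."""

    atom_name: str
    element: str
    coords: np.ndarray
    residue_index: int
    chain_id: str
    residue_name: str
    is_backbone: bool
    partial_charge: float = 0.0
    vdw_radius: float = 0.0
    vdw_epsilon: float = 0.0


class ComplexStructure:
    """Atoms/residues/chains of one complex model, coordinates in Angstrom."""

    def __init__(self, chain_ids, atom_name, element, chain_index, res_index,
                 res_name, coords, orig_resnum=None, charge=None, radius=None,
                 epsilon=None, provenance: str = ""):
        self.chain_ids: list[str] = list(chain_ids)
        self.atom_name: list[str] = list(atom_name)
        self.element: list[str] = list(element)
        self.chain_index = np.asarray(chain_index, dtype=np.int64)
        self.res_index = np.asarray(res_index, dtype=np.int64)
        self.res_name: list[str] = list(res_name)
        self.coords = np.array(coords, dtype=np.float64)
        n = len(self.atom_name)
        self.orig_resnum = (np.asarray(orig_resnum, dtype=np.int64)
                            if orig_resnum is not None else self.res_index.copy())
        self.charge = (np.asarray(charge, dtype=np.float64)
                       if charge is not None else None)
        self.radius = (np.asarray(radius, dtype=np.float64)
                       if radius is not None else None)
        self.epsilon = (np.asarray(epsilon, dtype=np.float64)
                        if epsilon is not None else None)
        self.provenance = provenance
        if self.coords.shape != (n, 3):
            raise MalformedPDB("coordinate array shape mismatch")
        self._index: dict | None = None

    # -- basic properties --------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def n_chains(self) -> int:
        return len(self.chain_ids)

    @property
    def is_backbone(self) -> np.ndarray:
        return np.array([a in chem.BACKBONE_ATOMS for a in self.atom_name])

    @property
    def atoms(self) -> list[AtomRecord]:
        return [self.atom_record(i) for i in range(self.n_atoms)]

    def atom_record(self, i: int) -> AtomRecord:
        return AtomRecord(
            atom_name=self.atom_name[i],
            element=self.element[i],
            coords=self.coords[i].copy(),
            residue_index=int(self.res_index[i]),
            chain_id=self.chain_ids[self.chain_index[i]],
            residue_name=self.res_name[i],
            is_backbone=self.atom_name[i] in chem.BACKBONE_ATOMS,
            partial_charge=float(self.charge[i]) if self.charge is not None else 0.0,
            vdw_radius=float(self.radius[i]) if self.radius is not None else 0.0,
            vdw_epsilon=float(self.epsilon[i]) if self.epsilon is not None else 0.0,
        )

    # -- lookup helpers ------------------------------------------------------
    def _build_index(self):
        idx = {}
        for i in range(self.n_atoms):
            key = (self.chain_ids[self.chain_index[i]], int(self.res_index[i]),
                   self.atom_name[i])
            if key in idx:
                raise MalformedPDB(f"duplicate atom {key}")
            idx[key] = i
        self._index = idx

    def atom_index(self, chain_id: str, residue_index: int, atom_name: str) -> int:
        if self._index is None:
            self._build_index()
        return self._index[(chain_id, residue_index, atom_name)]

    def has_atom(self, chain_id: str, residue_index: int, atom_name: str) -> bool:
        if self._index is None:
            self._build_index()
        return (chain_id, residue_index, atom_name) in self._index

    def chain_atoms(self, chain_id: str) -> np.ndarray:
        ci = self.chain_ids.index(chain_id)
        return np.nonzero(self.chain_index == ci)[0]

    def residues(self, chain_id: str | None = None):
        """Yield (chain_id, residue_index, residue_name, atom index array)."""
        chains = [chain_id] if chain_id is not None else self.chain_ids
        for cid in chains:
            ci = self.chain_ids.index(cid)
            mask = self.chain_index == ci
            for ri in np.unique(self.res_index[mask]):
                sel = np.nonzero(mask & (self.res_index == ri))[0]
                yield cid, int(ri), self.res_name[sel[0]], sel

    def residue_list(self) -> list[tuple[str, int]]:
        return [(cid, ri) for cid, ri, _rn, _sel in self.residues()]

    def residue_name_of(self, chain_id: str, residue_index: int) -> str:
        return self.res_name[self.atom_index(chain_id, residue_index, "CA")]

    def ca_indices(self, chain_id: str) -> np.ndarray:
        sel = self.chain_atoms(chain_id)
        return sel[[self.atom_name[i] == "CA" for i in sel]]

    def sequence(self, chain_id: str) -> str:
        letters = []
        for _cid, _ri, rn, _sel in self.residues(chain_id):
            letters.append(chem.THREE_TO_ONE.get(rn, "X"))
        return "".join(letters)

    @property
    def sequences(self) -> dict:
        return {cid: self.sequence(cid) for cid in self.chain_ids}

    # -- edit helpers --------------------------------------------------------
    def copy(self) -> "ComplexStructure":
        out = ComplexStructure(
            self.chain_ids, self.atom_name, self.element,
            self.chain_index.copy(), self.res_index.copy(), self.res_name,
            self.coords.copy(), self.orig_resnum.copy(),
            None if self.charge is None else self.charge.copy(),
            None if self.radius is None else self.radius.copy(),
            None if self.epsilon is None else self.epsilon.copy(),
            self.provenance,
        )
        return out

    def with_coords(self, coords: np.ndarray,
                    provenance: str | None = None) -> "ComplexStructure":
        out = self.copy()
        out.coords = np.array(coords, dtype=np.float64)
        if out.coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate shape mismatch")
        if provenance is not None:
            out.provenance = provenance
        return out

    # -- validation ----------------------------------------------------------
    def validate(self):
        if not np.all(np.isfinite(self.coords)):
            raise MalformedPDB("non-finite coordinates")
        if self._index is None:
            self._build_index()  # raises on duplicates
        for cid, ri, _rn, sel in self.residues():
            names = {self.atom_name[i] for i in sel}
            missing = set(chem.BACKBONE_ATOMS) - names
            if missing:
                raise IncompleteBackbone(
                    f"residue {cid}{ri} missing backbone atoms {sorted(missing)}")
        return self


def set_sidechain_chis(structure: ComplexStructure, chain_id: str,
                       residue_index: int, chis) -> None:
    """Rebuild one residue's side chain in place from chi angles."""
    rname = structure.residue_name_of(chain_id, residue_index)
    bb = {name: structure.coords[structure.atom_index(chain_id,
                                                      residue_index, name)]
          for name in ("N", "CA", "C")}
    for name, xyz in chem.build_sidechain(rname, bb, chis).items():
        if structure.has_atom(chain_id, residue_index, name):
            structure.coords[
                structure.atom_index(chain_id, residue_index, name)] = xyz


def from_residue_dicts(residues, provenance: str = "") -> ComplexStructure:
    """Build a ComplexStructure from a list of residue tuples.

    Each tuple: (chain_id, residue_name, {atom_name: xyz}, orig_resnum).
    Atoms are emitted in canonical order (backbone, CB, template order);
    atoms absent from the dict are skipped.
    """
    if not residues:
        raise MalformedPDB("no standard protein residues found")
    chain_ids: list[str] = []
    atom_name, element, chain_index, res_index, res_name = [], [], [], [], []
    orig = []
    coords = []
    counters: dict[str, int] = {}
    for cid, rname, atom_map, orig_num in residues:
        if cid not in chain_ids:
            chain_ids.append(cid)
            counters[cid] = 0
        counters[cid] += 1
        ri = counters[cid]
        ci = chain_ids.index(cid)
        order = [n for n in chem.residue_atom_names(rname) if n in atom_map]
        extra = [n for n in atom_map if n not in order]
        for name in order + sorted(extra):
            atom_name.append(name)
            element.append(chem.atom_element(rname, name)
                           if name in chem.residue_atom_names(rname)
                           else name[0])
            chain_index.append(ci)
            res_index.append(ri)
            res_name.append(rname)
            orig.append(orig_num)
            coords.append(np.asarray(atom_map[name], dtype=np.float64))
    return ComplexStructure(chain_ids, atom_name, element, chain_index,
                            res_index, res_name, np.array(coords),
                            orig_resnum=orig, provenance=provenance)
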