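"""CAPRI-style model quality assessment.

Computes ligand RMSD (backbone RMSD of the ligand after superposing the
receptor), interface RMSD (backbone RMSD over reference-defined interface
residues after superposing on them) and the fraction of native contacts
F_nat, then classifies the model as high/medium/acceptable/incorrect.

Backbone = N, CA, C, O.  The interface for I-RMSD uses any inter-chain
heavy-atom contact within 10 A on the reference; native contacts use a
5 A heavy-atom cutoff.  For homo-complexes all chain assignments
consistent with sequence identity are tried and the best value per metric
is reported.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (DomainError, EmptyInterface, MappingError,
                     NoNativeContacts)
from .structure import ComplexStructure
from .structure_io import apply_transform, kabsch_fit

BACKBONE = ("N", "CA", "C", "O")
IRMSD_CUTOFF = 10.0
CONTACT_CUTOFF = 5.0


@dataclass
class QualityMetrics:
    l_rmsd: float
    i_rmsd: float
    f_nat: float
    capri_class: str

    def row(self) -> str:
        return (f"{self.l_rmsd:.3f}\t{self.i_rmsd:.3f}\t{self.f_nat:.4f}\t"
                f"{self.capri_class}")


@dataclass
class ChainMapping:
    """Receptor/ligand roles plus a model-chain -> reference-chain map."""

    receptor_model: list
    ligand_model: list
    chain_map: dict                      # model chain id -> reference chain id

    def reference_chain(self, model_chain: str) -> str:
        return self.chain_map[model_chain]


def _check_pairing(model, reference, mapping: ChainMapping):
    for mc, rc in mapping.chain_map.items():
        if model.sequence(mc) != reference.sequence(rc):
            raise MappingError(
                f"model chain {mc} and reference chain {rc} differ in "
                "sequence")


def auto_mapping(model: ComplexStructure, reference: ComplexStructure,
                 receptor_chains=None, ligand_chains=None) -> ChainMapping:
    """Deterministic default mapping.

    Receptor is the chain with the most atoms (tie broken by input order)
    unless roles are given.  Model chains are matched to reference chains
    of identical sequence, same-id matches preferred.
    """
    if set(model.sequences.values()) != set(reference.sequences.values()):
        raise MappingError("model and reference sequences do not match")
    chain_map = {}
    used = set()
    for mc in model.chain_ids:
        seq = model.sequence(mc)
        cands = [rc for rc in reference.chain_ids
                 if rc not in used and reference.sequence(rc) == seq]
        if not cands:
            raise MappingError(f"no reference chain matches model chain {mc}")
        pick = mc if mc in cands else cands[0]
        chain_map[mc] = pick
        used.add(pick)
    if receptor_chains is None:
        sizes = [(len(model.chain_atoms(c)), model.chain_ids.index(c), c)
                 for c in model.chain_ids]
        receptor = max(sizes, key=lambda t: (t[0], -t[1]))[2]
        receptor_chains = [receptor]
    receptor_chains = list(receptor_chains)
    if ligand_chains is None:
        ligand_chains = [c for c in model.chain_ids
                         if c not in receptor_chains]
    mapping = ChainMapping(receptor_chains, list(ligand_chains), chain_map)
    _check_pairing(model, reference, mapping)
    return mapping


def _mapping_variants(model, reference, mapping: ChainMapping):
    """All chain maps consistent with sequence identity (roles fixed)."""
    groups: dict[str, list] = {}
    for rc in reference.chain_ids:
        groups.setdefault(reference.sequence(rc), []).append(rc)
    model_by_seq: dict[str, list] = {}
    for mc in mapping.receptor_model + mapping.ligand_model:
        model_by_seq.setdefault(model.sequence(mc), []).append(mc)
    per_seq_assignments = []
    seqs = list(model_by_seq)
    for seq in seqs:
        mcs = model_by_seq[seq]
        rcs = groups.get(seq, [])
        if len(rcs) < len(mcs):
            raise MappingError("reference lacks chains for some sequences")
        per_seq_assignments.append(list(itertools.permutations(rcs, len(mcs))))
    for combo in itertools.product(*per_seq_assignments):
        chain_map = {}
        ok = True
        used = set()
        for seq, perm in zip(seqs, combo):
            for mc, rc in zip(model_by_seq[seq], perm):
                if rc in used:
                    ok = False
                    break
                chain_map[mc] = rc
                used.add(rc)
            if not ok:
                break
        if ok:
            yield ChainMapping(mapping.receptor_model, mapping.ligand_model,
                               chain_map)


def _backbone_pairs(model, reference, mapping, chains):
    """Paired backbone coordinate arrays for the given model chains."""
    mx, rx = [], []
    for mc in chains:
        rc = mapping.reference_chain(mc)
        m_res = list(model.residues(mc))
        r_res = list(reference.residues(rc))
        if len(m_res) != len(r_res):
            raise MappingError(f"chain {mc}: residue count mismatch")
        for (mcid, mri, mrn, msel), (rcid, rri, rrn, rsel) in zip(m_res,
                                                                  r_res):
            if mrn != rrn:
                raise MappingError(
                    f"residue type mismatch {mrn} vs {rrn} at {mc}{mri}")
            m_map = {model.atom_name[i]: i for i in msel}
            r_map = {reference.atom_name[i]: i for i in rsel}
            for name in BACKBONE:
                if name in m_map and name in r_map:
                    mx.append(model.coords[m_map[name]])
                    rx.append(reference.coords[r_map[name]])
    return np.array(mx), np.array(rx)


def _rmsd(a, b):
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def ligand_rmsd(model: ComplexStructure, reference: ComplexStructure,
                mapping: ChainMapping) -> float:
    """Backbone RMSD of the ligand after receptor superposition."""
    _check_pairing(model, reference, mapping)
    best = None
    for var in _mapping_variants(model, reference, mapping):
        rec_m, rec_r = _backbone_pairs(model, reference, var,
                                       var.receptor_model)
        lig_m, lig_r = _backbone_pairs(model, reference, var,
                                       var.ligand_model)
        R, t, _ = kabsch_fit(rec_m, rec_r)
        val = _rmsd(apply_transform(lig_m, R, t), lig_r)
        best = val if best is None else min(best, val)
    return best


def _reference_interface_residues(reference, mapping,
                                  cutoff=IRMSD_CUTOFF):
    """(ref chain, residue) pairs with any inter-chain heavy-atom contact."""
    members = set()
    chains = list(reference.chain_ids)
    for a in range(len(chains)):
        for b in range(a + 1, len(chains)):
            ra = list(reference.residues(chains[a]))
            rb = list(reference.residues(chains[b]))
            for cid_a, ri_a, _rn, sel_a in ra:
                xa = reference.coords[sel_a]
                for cid_b, ri_b, _rn2, sel_b in rb:
                    d = cdist(xa, reference.coords[sel_b])
                    if (d < cutoff).any():
                        members.add((cid_a, ri_a))
                        members.add((cid_b, ri_b))
    return members


def interface_rmsd(model: ComplexStructure, reference: ComplexStructure,
                   mapping: ChainMapping,
                   interface_cutoff: float = IRMSD_CUTOFF) -> float:
    """Backbone RMSD over reference-interface residues after superposing
    on those residues."""
    _check_pairing(model, reference, mapping)
    best = None
    for var in _mapping_variants(model, reference, mapping):
        members = _reference_interface_residues(reference, var,
                                                interface_cutoff)
        if not members:
            raise EmptyInterface("reference has no interface residues")
        inv = {rc: mc for mc, rc in var.chain_map.items()}
        mx, rx = [], []
        for (rc, ri) in sorted(members):
            mc = inv[rc]
            for name in BACKBONE:
                if (model.has_atom(mc, ri, name)
                        and reference.has_atom(rc, ri, name)):
                    mx.append(model.coords[model.atom_index(mc, ri, name)])
                    rx.append(
                        reference.coords[reference.atom_index(rc, ri, name)])
        mx, rx = np.array(mx), np.array(rx)
        R, t, _ = kabsch_fit(mx, rx)
        val = _rmsd(apply_transform(mx, R, t), rx)
        best = val if best is None else min(best, val)
    return best


def _residue_contacts(structure, chain_pairs, cutoff):
    """Inter-chain residue contact set {((c1,r1),(c2,r2))} (ordered pairs)."""
    contacts = set()
    for ca, cb in chain_pairs:
        for cid_a, ri_a, _rn, sel_a in structure.residues(ca):
            xa = structure.coords[sel_a]
            for cid_b, ri_b, _rn2, sel_b in structure.residues(cb):
                d = cdist(xa, structure.coords[sel_b])
                if (d < cutoff).any():
                    contacts.add(((ca, ri_a), (cb, ri_b)))
    return contacts


def fraction_native_contacts(model: ComplexStructure,
                             reference: ComplexStructure,
                             mapping: ChainMapping,
                             contact_cutoff: float = CONTACT_CUTOFF) -> float:
    """|native contacts reproduced| / |native contacts| (5 A heavy-atom)."""
    _check_pairing(model, reference, mapping)
    best = None
    for var in _mapping_variants(model, reference, mapping):
        rec_r = [var.chain_map[c] for c in var.receptor_model]
        lig_r = [var.chain_map[c] for c in var.ligand_model]
        ref_pairs = [(a, b) for a in rec_r for b in lig_r]
        native = _residue_contacts(reference, ref_pairs, contact_cutoff)
        if not native:
            raise NoNativeContacts("reference has no inter-chain contacts")
        mod_pairs = [(a, b) for a in var.receptor_model
                     for b in var.ligand_model]
        model_contacts = _residue_contacts(model, mod_pairs, contact_cutoff)
        mapped = {((var.chain_map[a], ra), (var.chain_map[b], rb))
                  for ((a, ra), (b, rb)) in model_contacts}
        val = len(native & mapped) / len(native)
        best = val if best is None else max(best, val)
    return best


def capri_classify(l_rmsd: float, i_rmsd: float, f_nat: float) -> str:
    """CAPRI tiers with strict inequalities and high>medium>acceptable
    precedence."""
    if l_rmsd < 0 or i_rmsd < 0 or not 0.0 <= f_nat <= 1.0:
        raise DomainError("metrics out of domain")
    if (l_rmsd < 1.0 or i_rmsd < 1.0) and f_nat > 0.5:
        return "high"
    if (l_rmsd < 5.0 or i_rmsd < 2.0) and f_nat > 0.3:
        return "medium"
    if (l_rmsd < 10.0 or i_rmsd < 4.0) and f_nat > 0.1:
        return "acceptable"
    return "incorrect"


def assess(model: ComplexStructure, reference: ComplexStructure,
           mapping: ChainMapping | None = None,
           interface_cutoff: float = IRMSD_CUTOFF,
           contact_cutoff: float = CONTACT_CUTOFF) -> QualityMetrics:
    """All three CAPRI metrics plus the quality class."""
    if mapping is None:
        mapping = auto_mapping(model, reference)
    l = ligand_rmsd(model, reference, mapping)
    i = interface_rmsd(model, reference, mapping, interface_cutoff)
    f = fraction_native_contacts(model, reference, mapping, contact_cutoff)
    return QualityMetrics(l, i, f, capri_classify(l, i, f))
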