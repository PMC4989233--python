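"""Synthetic toy complexes, decoys and parameter tables.

The fixture generator builds ideal-geometry alpha-helical chains
(phi = -57, psi = -47), dresses them with rotamer-library side chains and
packs them as a dimer or a Cn homo-oligomer by scanning the inter-chain
separation until the interface is clash-free at full vdW radii while still
containing at least five interfacial residues per chain.  Decoys perturb
the ligand chain rigidly and/or scramble interface side chains to random
rotamers, and come with their exact quality metrics versus the reference.

Sequences are ALA-rich with larger side chains (LEU/PHE/ARG/...) mixed in
so that interface repacking has genuine work to do.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import chemistry as chem
from . import params as prm
from .assessment import assess, auto_mapping
from .errors import PackingFailure
from .restraints import detect_interface
from .structure import (ComplexStructure, from_residue_dicts,
                        set_sidechain_chis)
from .structure_io import apply_transform

HELIX_PHI = -57.0
HELIX_PSI = -47.0

# residue pools for "ALA-rich random" fixture sequences: heptad a/d
# positions carry large side chains so the interface is side-chain mediated
_FACE_POOL = ("LEU", "PHE", "ARG", "MET")
_FACE_WEIGHTS = (0.45, 0.25, 0.15, 0.15)
_BODY_POOL = ("ALA", "SER", "VAL", "THR", "GLY")
_BODY_WEIGHTS = (0.50, 0.18, 0.14, 0.12, 0.06)


@dataclass
class FixtureSpec:
    """Recipe for one toy complex."""

    chain_length: int = 12
    n_chains: int = 2
    symmetry: int | None = None          # Cn order; None = heteromer pose
    sequence: str | None = None          # 1-letter string, None = random
    decoy_perturbation: tuple = (0.0, 0.0, 0.0)  # (rot deg, trans A, frac)
    seed: int = 0

    def validate(self):
        if self.chain_length < 5:
            raise ValueError("chain_length must be >= 5")
        if any(m < 0 for m in self.decoy_perturbation):
            raise ValueError("perturbation magnitudes must be >= 0")
        if self.symmetry is not None and self.symmetry != self.n_chains:
            raise ValueError("symmetry order must equal n_chains")
        return self


def random_sequence(length: int, rng) -> list:
    """ALA-rich sequence with large residues at heptad a/d positions."""
    seq = []
    for i in range(length):
        if i % 7 in (0, 3):
            seq.append(str(rng.choice(_FACE_POOL, p=_FACE_WEIGHTS)))
        else:
            seq.append(str(rng.choice(_BODY_POOL, p=_BODY_WEIGHTS)))
    return seq


def _face_indices(seq3: list) -> list:
    """Indices of the third of residues with the largest side chains."""
    sizes = [(-(len(chem.SIDECHAIN_TEMPLATES[rn]) + int(chem.has_cb(rn))), i)
             for i, rn in enumerate(seq3)]
    sizes.sort()
    take = max(3, len(seq3) // 3)
    return sorted(i for _s, i in sizes[:take])


def _orient_face(residues, face_idx, direction):
    """Rotate a z-axis-aligned chain about z so the mean CA->CB direction
    of the face residues points along *direction* (unit xy vector)."""
    vecs = []
    for i in face_idx:
        rname, amap = residues[i]
        if "CB" in amap:
            v = amap["CB"] - amap["CA"]
            vecs.append(v[:2])
    if not vecs:
        return residues
    mean = np.mean(vecs, axis=0)
    if np.linalg.norm(mean) < 1e-9:
        return residues
    cur = np.arctan2(mean[1], mean[0])
    want = np.arctan2(direction[1], direction[0])
    return _transform_residues(residues, _rot_z(np.degrees(want - cur)),
                               np.zeros(3))


def sample_rotamer(library: prm.RotamerLibrary, restype: str, rng):
    rots = library.get(restype)
    probs = np.array([p for _c, p in rots])
    k = int(rng.choice(len(rots), p=probs / probs.sum()))
    return rots[k][0]


def build_helix_chain(seq3: list, library: prm.RotamerLibrary, rng,
                      phi: float = HELIX_PHI, psi: float = HELIX_PSI):
    """Residue dicts for one ideal helix with rotamer side chains."""
    g = chem.BB_GEOM
    residues = []
    prev = None
    for i, rname in enumerate(seq3):
        if prev is None:
            n = np.zeros(3)
            ca = np.array([g["N_CA"], 0.0, 0.0])
            th = np.radians(180.0 - g["ang_N_CA_C"])
            c = ca + g["CA_C"] * np.array([np.cos(th), np.sin(th), 0.0])
        else:
            n = chem.place_atom(prev["N"], prev["CA"], prev["C"],
                                g["C_N"], g["ang_CA_C_N"], psi)
            ca = chem.place_atom(prev["CA"], prev["C"], n,
                                 g["N_CA"], g["ang_C_N_CA"], g["omega"])
            c = chem.place_atom(prev["C"], n, ca,
                                g["CA_C"], g["ang_N_CA_C"], phi)
        o = chem.place_atom(n, ca, c, g["C_O"], g["ang_CA_C_O"], psi + 180.0)
        atom_map = {"N": n, "CA": ca, "C": c, "O": o}
        chis = sample_rotamer(library, rname, rng)
        atom_map.update(chem.build_sidechain(rname, atom_map, chis))
        residues.append((rname, atom_map))
        prev = atom_map
    return residues


def _as_struct(chains, provenance):
    rows = []
    for cid, residues in chains:
        for k, (rname, amap) in enumerate(residues, start=1):
            rows.append((cid, rname, amap, k))
    return from_residue_dicts(rows, provenance=provenance)


def _center_on_axis(residues):
    """Center the chain and align its CA axis with z."""
    cas = np.array([amap["CA"] for _r, amap in residues])
    centroid = cas.mean(axis=0)
    axis = cas[-1] - cas[0]
    axis /= np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    if s < 1e-9:
        R = np.eye(3)
    else:
        cterm = float(np.dot(axis, z))
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - cterm) / s ** 2)
    out = []
    for rname, amap in residues:
        out.append((rname, {k: R @ (x - centroid) for k, x in amap.items()}))
    return out


def _transform_residues(residues, R, t):
    return [(rn, {k: R @ x + t for k, x in amap.items()})
            for rn, amap in residues]


def _rot_z(deg):
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a), 0],
                     [np.sin(a), np.cos(a), 0],
                     [0, 0, 1.0]])


def _rot_x(deg):
    a = np.radians(deg)
    return np.array([[1.0, 0, 0],
                     [0, np.cos(a), -np.sin(a)],
                     [0, np.sin(a), np.cos(a)]])


def _rot_y(deg):
    a = np.radians(deg)
    return np.array([[np.cos(a), 0, np.sin(a)],
                     [0, 1.0, 0],
                     [-np.sin(a), 0, np.cos(a)]])


def _clashing_residues(structure, ff, overlap_factor=0.8, vdw_scale=1.0):
    """Residues involved in any inter-chain atomic overlap."""
    radii = np.array([ff.vdw(e)[0] for e in structure.element])
    bad = set()
    for a in range(structure.n_chains):
        for b in range(a + 1, structure.n_chains):
            ia = structure.chain_atoms(structure.chain_ids[a])
            ib = structure.chain_atoms(structure.chain_ids[b])
            d = cdist(structure.coords[ia], structure.coords[ib])
            lim = (radii[ia][:, None] + radii[ib][None, :]) \
                * vdw_scale * overlap_factor
            for ka, kb in zip(*np.nonzero(d < lim)):
                i, j = ia[ka], ib[kb]
                bad.add((structure.chain_ids[structure.chain_index[i]],
                         int(structure.res_index[i])))
                bad.add((structure.chain_ids[structure.chain_index[j]],
                         int(structure.res_index[j])))
    return bad


def _interchain_clash(structure, ff, overlap_factor=0.8, vdw_scale=1.0):
    return bool(_clashing_residues(structure, ff, overlap_factor, vdw_scale))


def _overlap_score(structure, ff):
    """Total inter-chain overlap depth (0 = clash-free)."""
    radii = np.array([ff.vdw(e)[0] for e in structure.element])
    score = 0.0
    for a in range(structure.n_chains):
        for b in range(a + 1, structure.n_chains):
            ia = structure.chain_atoms(structure.chain_ids[a])
            ib = structure.chain_atoms(structure.chain_ids[b])
            d = cdist(structure.coords[ia], structure.coords[ib])
            lim = (radii[ia][:, None] + radii[ib][None, :]) * 0.8
            over = lim - d
            score += float(over[over > 0].sum())
    return score


def _resolve_clashes(structure, ff, library, rng, rounds: int = 6,
                     symmetric: bool = False) -> bool:
    """Remove inter-chain overlaps by greedy rotamer search over the
    clashing residues.  With symmetric=True the same rotamer is applied to
    the corresponding residue of every chain (keeps Cn copies identical).
    Returns True on success (edits in place)."""
    for _ in range(rounds):
        bad = _clashing_residues(structure, ff)
        if not bad:
            return True
        if symmetric:
            bad = {(cid, ri) for (_c, ri) in bad
                   for cid in structure.chain_ids}
        improved = False
        order = sorted({ri for (_c, ri) in bad} if symmetric else bad)
        rng.shuffle(order)
        for item in order:
            if symmetric:
                ri = item
                targets = [(cid, ri) for cid in structure.chain_ids]
                rname = structure.residue_name_of(structure.chain_ids[0], ri)
            else:
                cid, ri = item
                targets = [(cid, ri)]
                rname = structure.residue_name_of(cid, ri)
            if chem.n_chi(rname) == 0:
                continue
            saved = structure.coords.copy()
            best_score = _overlap_score(structure, ff)
            best_coords = None
            for chis, _p in library.get(rname):
                structure.coords[:] = saved
                for (tc, tr) in targets:
                    set_sidechain_chis(structure, tc, tr, chis)
                s = _overlap_score(structure, ff)
                if s < best_score - 1e-12:
                    best_score = s
                    best_coords = structure.coords.copy()
            if best_coords is not None:
                structure.coords[:] = best_coords
                improved = True
            else:
                structure.coords[:] = saved
        if not improved:
            break
    return not _clashing_residues(structure, ff)


def make_reference_complex(spec: FixtureSpec,
                           library: prm.RotamerLibrary | None = None,
                           ff: prm.ForceFieldTable | None = None,
                           min_interface: int = 5) -> ComplexStructure:
    """Deterministic packed toy complex satisfying the fixture contract."""
    spec.validate()
    library = library or prm.load_rotamer_library()
    ff = ff or prm.load_forcefield()
    rng = np.random.default_rng(spec.seed)
    if spec.sequence is not None:
        seq3 = [chem.ONE_TO_THREE[c] for c in spec.sequence]
    else:
        seq3 = random_sequence(spec.chain_length, rng)
    base = _center_on_axis(build_helix_chain(seq3, library, rng))
    chain_ids = [chr(ord("A") + k) for k in range(spec.n_chains)]

    def _min_interface_count(st):
        iface = detect_interface(st)
        return min(sum(1 for (c, _r) in iface.members if c == cid)
                   for cid in chain_ids)

    def _sidechain_contact_fraction(st):
        """Fraction of inter-chain residue contacts that need atoms
        beyond CB; high values make the interface repack-sensitive."""
        mapping = auto_mapping(st, st)
        total = dep = 0
        for ca_ in mapping.receptor_model:
            for cb_ in mapping.ligand_model:
                for _c1, r1, rn1, s1 in st.residues(ca_):
                    x1 = st.coords[s1]
                    core1 = [k for k, i in enumerate(s1)
                             if st.atom_name[i] in
                             ("N", "CA", "C", "O", "CB")]
                    for _c2, r2, rn2, s2 in st.residues(cb_):
                        d = cdist(x1, st.coords[s2])
                        if not (d < 5.0).any():
                            continue
                        total += 1
                        core2 = [k for k, i in enumerate(s2)
                                 if st.atom_name[i] in
                                 ("N", "CA", "C", "O", "CB")]
                        if not (d[np.ix_(core1, core2)] < 5.0).any():
                            dep += 1
        return dep / total if total else 0.0

    if spec.symmetry is not None:
        n = spec.symmetry
        fallback = None
        for radius in np.arange(4.0, 16.01, 0.25):
            for fang in (0.0, 30.0, -30.0, 60.0, -60.0, 90.0, -90.0,
                         120.0, 180.0):
                for tilt in (0.0, 12.0, -12.0):
                    direction = np.array([-np.cos(np.radians(fang)),
                                          np.sin(np.radians(fang))])
                    posed = _orient_face(base, _face_indices(seq3),
                                         direction)
                    if tilt:
                        # tilt the helix axis off the symmetry axis, as in
                        # a supercoiled bundle; applied identically to all
                        # copies so Cn closure is preserved
                        posed = _transform_residues(posed, _rot_y(tilt),
                                                    np.zeros(3))
                    chains = []
                    for k in range(n):
                        R = _rot_z(360.0 * k / n)
                        t = R @ np.array([radius, 0.0, 0.0])
                        chains.append((chain_ids[k],
                                       _transform_residues(posed, R, t)))
                    st = _as_struct(chains,
                                    f"fixture-C{n}-seed{spec.seed}")
                    if not _resolve_clashes(st, ff, library, rng,
                                            symmetric=True):
                        continue
                    if _min_interface_count(st) < min_interface:
                        continue
                    if _sidechain_contact_fraction(st) >= 0.5:
                        return st
                    if fallback is None:
                        fallback = st
        if fallback is not None:
            return fallback
        raise PackingFailure("could not pack symmetric oligomer")

    if spec.n_chains != 2:
        raise PackingFailure("heteromer fixtures support 2 chains")
    # second chain: fresh sequence/rotamers, antiparallel alongside chain
    # A, with both large-side-chain faces turned into the interface and a
    # scan over axial stagger and face angle to let the knobs interdigitate
    base = _orient_face(base, _face_indices(seq3), np.array([1.0, 0.0]))
    seq3b = (random_sequence(spec.chain_length, rng)
             if spec.sequence is None else seq3)
    other = _center_on_axis(build_helix_chain(seq3b, library, rng))
    flip = _rot_x(180.0)
    fallback = None
    for sep in np.arange(8.5, 16.01, 0.5):
        for zoff in (0.0, 1.5, 2.7, -1.5, -2.7):
            for fang in (0.0, 30.0, -30.0, 60.0, -60.0, 90.0):
                direction = np.array([-np.cos(np.radians(fang)),
                                      np.sin(np.radians(fang))])
                posed = _orient_face(other, _face_indices(seq3b), direction)
                chains = [(chain_ids[0], base),
                          (chain_ids[1], _transform_residues(
                              posed, flip, np.array([sep, 0.0, zoff])))]
                st = _as_struct(chains, f"fixture-dimer-seed{spec.seed}")
                if not _resolve_clashes(st, ff, library, rng):
                    continue
                if _min_interface_count(st) < min_interface:
                    continue
                if _sidechain_contact_fraction(st) >= 0.5:
                    return st
                if fallback is None:
                    fallback = st
    if fallback is not None:
        return fallback
    raise PackingFailure("could not pack dimer without clash")


# --------------------------------------------------------------------------
# decoys
# --------------------------------------------------------------------------

def make_decoy(reference: ComplexStructure, perturbation, seed: int = 0,
               library: prm.RotamerLibrary | None = None):
    """Rigid-body + side-chain-scramble decoy with its exact metrics.

    perturbation = (rotation degrees, translation A, scramble fraction).
    The rigid perturbation is applied to the ligand chain (auto receptor/
    ligand roles); the scramble reassigns that fraction of interface
    residues (both sides) to random library rotamers.
    """
    rot_deg, trans, frac = perturbation
    library = library or prm.load_rotamer_library()
    rng = np.random.default_rng(seed)
    decoy = reference.copy()
    decoy.provenance = f"decoy-of({reference.provenance})"
    mapping = auto_mapping(decoy, reference)
    lig_atoms = np.concatenate(
        [decoy.chain_atoms(c) for c in mapping.ligand_model])
    if rot_deg > 0 or trans > 0:
        centroid = decoy.coords[lig_atoms].mean(axis=0)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        from scipy.spatial.transform import Rotation
        R = Rotation.from_rotvec(np.radians(rot_deg) * axis).as_matrix()
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        t = trans * direction
        decoy.coords[lig_atoms] = apply_transform(
            decoy.coords[lig_atoms] - centroid, R, centroid + t)
    if frac > 0:
        iface = detect_interface(reference)
        members = iface.sorted_members()
        scramblable = [m for m in members
                       if chem.n_chi(reference.residue_name_of(*m)) > 0]
        k = int(round(frac * len(scramblable)))
        chosen = [scramblable[i] for i in
                  rng.choice(len(scramblable), size=min(k, len(scramblable)),
                             replace=False)]
        for cid, ri in sorted(chosen):
            rname = decoy.residue_name_of(cid, ri)
            rots = library.get(rname)
            if len(rots) > 1:
                # reassign to a rotamer different from the current one
                amap = {decoy.atom_name[i]: decoy.coords[i]
                        for i in decoy.chain_atoms(cid)
                        if decoy.res_index[i] == ri}
                cur = np.array(chem.measure_chis(rname, amap))
                cands = [c for c, _p in rots
                         if np.max(np.abs((np.array(c) - cur + 180) % 360
                                          - 180)) > 15.0]
                if not cands:
                    cands = [c for c, _p in rots]
                chis = cands[int(rng.integers(len(cands)))]
            else:
                chis = rots[0][0]
            set_sidechain_chis(decoy, cid, ri, chis)
    metrics = assess(decoy, reference)
    return decoy, metrics


def scrambled_decoy_cases(n_cases: int, start_seed: int = 0,
                          chain_length: int = 10, max_fnat: float = 0.75,
                          attempts: int = 6,
                          library: prm.RotamerLibrary | None = None):
    """Yield (fixture_seed, reference, decoy, metrics) for complexes whose
    interfaces respond to side-chain scrambling.

    Fixture interfaces vary in how much of their contact set is carried by
    rotatable side chains; a decoy that retains nearly all native contacts
    after scrambling cannot demonstrate contact recovery.  This scans
    fixture seeds and keeps those for which a fully scrambled decoy drops
    below *max_fnat* native contacts (selection uses only the decoy's own
    metrics, computed before any refinement).
    """
    library = library or prm.load_rotamer_library()
    found = 0
    seed = start_seed
    while found < n_cases:
        try:
            ref = make_reference_complex(
                FixtureSpec(chain_length=chain_length, n_chains=2,
                            seed=seed), library=library)
        except PackingFailure:
            seed += 1
            continue
        for k in range(attempts):
            decoy, metrics = make_decoy(ref, (0.0, 0.0, 1.0),
                                        seed=seed * 100 + k,
                                        library=library)
            if metrics.f_nat <= max_fnat:
                yield seed, ref, decoy, metrics
                found += 1
                break
        seed += 1


def make_parameter_tables(seed: int = 0):
    """(ForceFieldTable, RotamerLibrary, StatTables) with a synthetic,
    smooth non-zero pair potential (the packaged default table is zero)."""
    ff = prm.load_forcefield()
    library = prm.load_rotamer_library()
    tables = prm.default_tables(library)
    rng = np.random.default_rng(seed)
    nbins = tables.pairstat.shape[2]
    centers = (np.arange(nbins) + 0.5) * prm.PAIRSTAT_BIN
    n = len(chem.AA3)
    depth = rng.uniform(-0.3, 0.1, size=(n, n))
    depth = 0.5 * (depth + depth.T)
    well = np.exp(-0.5 * ((centers - 6.0) / 1.5) ** 2)
    taper = np.clip((prm.PAIRSTAT_RMAX - centers) / 2.0, 0.0, 1.0)
    tables.pairstat = depth[:, :, None] * (well * taper)[None, None, :]
    return ff, library, tables
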