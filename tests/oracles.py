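"""Independent brute-force reference implementations.

Everything here is written as plain double loops over atoms/residues with
its own SVD-based superposition, deliberately sharing no code with the
vectorized implementations it checks.
"""
from __future__ import annotations

import numpy as np

from refinecomplex import chemistry as chem
from refinecomplex import params as prm
from refinecomplex.energy import (COULOMB_K, HBOND_AMIN_DEG,
                                  HBOND_ARANGE_DEG, HBOND_DMAX, HBOND_DMIN,
                                  HBOND_STRENGTH, NB_CUTOFF, NONPOLAR_GAMMA,
                                  NONPOLAR_PAD)

BACKBONE = ("N", "CA", "C", "O")


# --------------------------------------------------------------------------
# superposition / RMSD
# --------------------------------------------------------------------------

def kabsch_svd(P, Q):
    """Rigid transform (R, t) minimizing |R P + t - Q| via plain SVD."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def rmsd_after_fit(P, Q):
    R, t = kabsch_svd(P, Q)
    diff = (P @ R.T + t) - Q
    return float(np.sqrt((diff ** 2).sum() / len(P)))


def plain_rmsd(P, Q):
    diff = np.asarray(P) - np.asarray(Q)
    return float(np.sqrt((diff ** 2).sum() / len(P)))


# --------------------------------------------------------------------------
# interface / restraints
# --------------------------------------------------------------------------

def brute_interface(structure, cutoff=8.0):
    """All-pairs double loop over residues of different chains."""
    res = list(structure.residues())
    members = set()
    for a in range(len(res)):
        for b in range(len(res)):
            ca_, ra, _rna, sa = res[a]
            cb_, rb, _rnb, sb = res[b]
            if ca_ == cb_:
                continue
            xa = next(structure.coords[i] for i in sa
                      if structure.atom_name[i] == "CA")
            xb = next(structure.coords[i] for i in sb
                      if structure.atom_name[i] == "CA")
            if np.linalg.norm(xa - xb) < cutoff:
                members.add((ca_, ra))
                members.add((cb_, rb))
    return members


def brute_restraint_pairs(structure, cutoff=10.0):
    """Qualifying CA-CA and N-O atom-key pairs with reference distances."""
    atoms = []
    for cid, ri, _rn, sel in structure.residues():
        for i in sel:
            atoms.append((cid, ri, structure.atom_name[i],
                          structure.coords[i]))
    pairs = set()
    ca = [a for a in atoms if a[2] == "CA"]
    for i in range(len(ca)):
        for j in range(i + 1, len(ca)):
            d = np.linalg.norm(ca[i][3] - ca[j][3])
            if d < cutoff:
                pairs.add(((ca[i][0], ca[i][1], "CA"),
                           (ca[j][0], ca[j][1], "CA")))
    ns = [a for a in atoms if a[2] == "N"]
    os_ = [a for a in atoms if a[2] == "O"]
    for n in ns:
        for o in os_:
            if (n[0], n[1]) == (o[0], o[1]):
                continue
            if n[0] == o[0] and abs(n[1] - o[1]) <= 1:
                continue
            if np.linalg.norm(n[3] - o[3]) < cutoff:
                pairs.add(((n[0], n[1], "N"), (o[0], o[1], "O")))
    return pairs


# --------------------------------------------------------------------------
# energy terms (naive loops over the model's parameter arrays)
# --------------------------------------------------------------------------

def brute_nonbonded(model, X):
    """(vdw, coulomb, solv_polar, solv_nonpolar) by a naive double loop."""
    st = model.structure
    n = st.n_atoms
    excl = model.topology.excluded_pairs
    s14 = model.topology.scaled14_pairs
    e_vdw = e_cou = e_pol = e_np = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            c = 0.5 if (i, j) in s14 else 1.0
            r = float(np.linalg.norm(X[i] - X[j]))
            if r < NB_CUTOFF:
                rm = (st.radius[i] + st.radius[j]) * model.vdw_scale
                eps = np.sqrt(st.epsilon[i] * st.epsilon[j])
                x6 = (rm / r) ** 6
                e_vdw += c * eps * (x6 * x6 - 2 * x6)
                qq = COULOMB_K * st.charge[i] * st.charge[j]
                e_cou += c * qq / r
                e_pol += c * qq * (0.25 / r ** 2 - 1.0 / r)
            if st.element[i] in ("C", "S") and st.element[j] in ("C", "S"):
                rc = st.radius[i] + st.radius[j] + NONPOLAR_PAD
                if r < rc:
                    e_np += (NONPOLAR_GAMMA * c
                             * (1.0 - (r / rc) ** 2) ** 2)
    return e_vdw, e_cou, e_pol, e_np


def brute_bonded(model, X):
    top = model.topology
    e = 0.0
    for (i, j), r0 in zip(top.bond_idx, top.bond_r0):
        e += model.ff.k_bond * (np.linalg.norm(X[i] - X[j]) - r0) ** 2
    for (i, j, k), t0 in zip(top.angle_idx, top.angle_t0):
        th = np.radians(chem.measure_angle(X[i], X[j], X[k]))
        e += model.ff.k_angle * (th - t0) ** 2
    return float(e)


def brute_hbond(model, X):
    e = 0.0
    for dn, ao, ac in model._hb:
        r = float(np.linalg.norm(X[dn] - X[ao]))
        if not HBOND_DMIN < r < HBOND_DMAX:
            continue
        fd = np.sin(np.pi * (r - HBOND_DMIN)
                    / (HBOND_DMAX - HBOND_DMIN)) ** 2
        th = chem.measure_angle(X[ac], X[ao], X[dn])
        if not (HBOND_AMIN_DEG < th < HBOND_AMIN_DEG + HBOND_ARANGE_DEG):
            continue
        fa = np.sin(np.pi * (th - HBOND_AMIN_DEG) / HBOND_ARANGE_DEG) ** 2
        e -= HBOND_STRENGTH * fd * fa
    return float(e)


def _interp1_periodic(grid, x):
    n = len(grid)
    h = 360.0 / n
    s = (x + 180.0) / h
    i0 = int(np.floor(s)) % n
    f = s - np.floor(s)
    return (1 - f) * grid[i0] + f * grid[(i0 + 1) % n]


def brute_rama(model, X):
    e = 0.0
    R = model.tables.rama
    n = prm.N_GRID
    h = 360.0 / n
    for pq, qq in zip(model._phi, model._psi):
        phi = chem.measure_dihedral(*(X[i] for i in pq))
        psi = chem.measure_dihedral(*(X[i] for i in qq))
        sp, sq = (phi + 180.0) / h, (psi + 180.0) / h
        i0, j0 = int(np.floor(sp)) % n, int(np.floor(sq)) % n
        fp, fq = sp - np.floor(sp), sq - np.floor(sq)
        i1, j1 = (i0 + 1) % n, (j0 + 1) % n
        e += (R[i0, j0] * (1 - fp) * (1 - fq) + R[i1, j0] * fp * (1 - fq)
              + R[i0, j1] * (1 - fp) * fq + R[i1, j1] * fp * fq)
    return float(e)


def brute_rotamer(model, X):
    e = 0.0
    for quad, grid in zip(model._chi, model._chi_grids):
        chi = chem.measure_dihedral(*(X[i] for i in quad))
        e += _interp1_periodic(grid, chi)
    return float(e)


def brute_pairstat(model, X):
    e = 0.0
    nbins = model._ps_rows.shape[1]
    for (i, j), row in zip(zip(model._ps_i, model._ps_j), model._ps_rows):
        r = float(np.linalg.norm(X[i] - X[j]))
        s = min(max(r / prm.PAIRSTAT_BIN - 0.5, 0.0), nbins - 1 - 1e-12)
        i0 = int(np.floor(s))
        f = s - i0
        e += (1 - f) * row[i0] + f * row[min(i0 + 1, nbins - 1)]
    return float(e)


def brute_restraints(structure, restraints):
    X = structure.coords
    e_d = e_p = 0.0
    for r in restraints.distance:
        i = structure.atom_index(*r.atom_i)
        j = structure.atom_index(*r.atom_j)
        e_d += r.weight * (np.linalg.norm(X[i] - X[j]) - r.d0) ** 2
    for r in restraints.position:
        i = structure.atom_index(*r.atom_i)
        e_p += r.weight * float(np.sum((X[i] - r.r0) ** 2))
    return float(e_d), float(e_p)


# --------------------------------------------------------------------------
# CAPRI metrics
# --------------------------------------------------------------------------

def _bb_coords(structure, chain, n_res=None):
    out = []
    for cid, ri, _rn, sel in structure.residues(chain):
        amap = {structure.atom_name[i]: i for i in sel}
        for name in BACKBONE:
            if name in amap:
                out.append(structure.coords[amap[name]])
    return np.array(out)


def brute_lrmsd(model, reference, receptor, ligand):
    """Single-chain receptor/ligand, identity chain map."""
    rec_m = _bb_coords(model, receptor)
    rec_r = _bb_coords(reference, receptor)
    lig_m = _bb_coords(model, ligand)
    lig_r = _bb_coords(reference, ligand)
    R, t = kabsch_svd(rec_m, rec_r)
    return plain_rmsd(lig_m @ R.T + t, lig_r)


def brute_irmsd(model, reference, cutoff=10.0):
    res = list(reference.residues())
    members = set()
    for a in range(len(res)):
        for b in range(len(res)):
            ca_, ra, _r1, sa = res[a]
            cb_, rb, _r2, sb = res[b]
            if ca_ == cb_:
                continue
            for i in sa:
                for j in sb:
                    if np.linalg.norm(reference.coords[i]
                                      - reference.coords[j]) < cutoff:
                        members.add((ca_, ra))
                        members.add((cb_, rb))
                        break
                else:
                    continue
                break
    mx, rx = [], []
    for (cid, ri) in sorted(members):
        for name in BACKBONE:
            if model.has_atom(cid, ri, name):
                mx.append(model.coords[model.atom_index(cid, ri, name)])
                rx.append(
                    reference.coords[reference.atom_index(cid, ri, name)])
    return rmsd_after_fit(np.array(mx), np.array(rx))


def brute_fnat(model, reference, cutoff=5.0):
    def contacts(st):
        out = set()
        res = list(st.residues())
        for a in range(len(res)):
            for b in range(len(res)):
                ca_, ra, _r1, sa = res[a]
                cb_, rb, _r2, sb = res[b]
                if ca_ >= cb_:
                    continue
                hit = False
                for i in sa:
                    for j in sb:
                        if np.linalg.norm(st.coords[i]
                                          - st.coords[j]) < cutoff:
                            hit = True
                            break
                    if hit:
                        break
                if hit:
                    out.add(((ca_, ra), (cb_, rb)))
        return out

    native = contacts(reference)
    modelled = contacts(model)
    return len(native & modelled) / len(native)


def capri_rule(l, i, f):
    """Direct transcription of the published tier rule."""
    if (l < 1.0 or i < 1.0) and f > 0.5:
        return "high"
    if (l < 5.0 or i < 2.0) and f > 0.3:
        return "medium"
    if (l < 10.0 or i < 4.0) and f > 0.1:
        return "acceptable"
    return "incorrect"
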