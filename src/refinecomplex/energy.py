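"""Hybrid refinement energy: physics terms, knowledge-based terms, restraints.

The total energy is a linear combination of eleven terms, each with its own
weight: molecular-mechanics bonded energy, Lennard-Jones, Coulomb, polar and
non-polar implicit-solvation surrogates, a geometric backbone hydrogen-bond
term, a residue-pair statistical potential, backbone (phi/psi) and
side-chain (chi) torsion-preference terms, and the harmonic distance /
position restraint terms anchored to the input model.  Every term has an
analytic gradient; the per-term breakdown reproduces the weighted total to
machine precision.

Implementation notes
--------------------
* The Coulomb term is the bare 1/r interaction; the polar-solvation
  surrogate is the *difference* between a distance-dependent-dielectric
  (eps(r) = 4r) screened interaction and the bare one, so at unit weights
  the electrostatics pathway is exactly the screened 1/(4 r^2) form.
* The non-polar solvation surrogate rewards burial of hydrophobic (C/S)
  atom pairs with a smooth short-range contact function, a pairwise
  stand-in for a buried-surface-area term.
* Nonbonded interactions use a 12 A cutoff, exclude 1-2/1-3 bonded pairs
  and scale 1-4 pairs by 0.5.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np

from . import chemistry as chem
from . import params as prm
from .errors import NonFiniteEnergy
from .restraints import RestraintSet, resolve_atom
from .structure import ComplexStructure

COULOMB_K = 332.0636          # kcal mol^-1 A e^-2
NB_CUTOFF = 12.0              # A
SCALE_14 = 0.5
HBOND_STRENGTH = 1.5          # kcal/mol well depth scale
HBOND_DMIN, HBOND_DMAX = 2.6, 3.5
HBOND_AMIN_DEG, HBOND_ARANGE_DEG = 100.0, 100.0
NONPOLAR_GAMMA = -0.02        # kcal/mol per pair contact unit (burial reward)
NONPOLAR_PAD = 2.8            # A added to summed radii for the contact range
CLASH_OVERLAP_FACTOR = 0.8

TERM_NAMES = ("bonded", "vdw", "coulomb", "solv_polar", "solv_nonpolar",
              "hbond", "pairstat", "rama", "rotamer",
              "restraint_distance", "restraint_position")


@dataclass
class EnergyWeights:
    """Relative weights of the linear energy combination (all >= 0)."""

    bonded: float = 1.0
    vdw: float = 1.0
    coulomb: float = 1.0
    solv_polar: float = 1.0
    solv_nonpolar: float = 1.0
    hbond: float = 1.0
    pairstat: float = 1.0
    rama: float = 1.0
    rotamer: float = 1.0
    restraint_distance: float = 1.0
    restraint_position: float = 1.0

    def validate(self):
        for f in dc_fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"weight {f.name} must be >= 0")
        return self

    def as_dict(self):
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyWeights":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class EnergyBreakdown:
    """Unweighted per-term energies, the weights used, and the total."""

    terms: dict
    weights: EnergyWeights
    total: float

    def weighted(self, name: str) -> float:
        return self.terms[name] * getattr(self.weights, name)


# --------------------------------------------------------------------------
# vectorized geometry derivatives
# --------------------------------------------------------------------------

def _cross(a, b):
    """Row-wise cross product (faster than np.cross for (n,3) arrays)."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _scatter_add(g, idx, vals):
    """g[idx] += vals without the np.add.at overhead."""
    n = g.shape[0]
    for d in range(3):
        g[:, d] += np.bincount(idx, weights=vals[:, d], minlength=n)


def angles_and_grads(X, idx):
    """Angles (rad) for index triplets (i,j,k) and gradients wrt each atom."""
    i, j, k = idx[:, 0], idx[:, 1], idx[:, 2]
    u = X[i] - X[j]
    v = X[k] - X[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    cosq = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
    sinq = np.sqrt(np.maximum(1.0 - cosq ** 2, 1e-12))
    theta = np.arccos(cosq)
    gi = (cosq[:, None] * uh - vh) / (nu * sinq)[:, None]
    gk = (cosq[:, None] * vh - uh) / (nv * sinq)[:, None]
    gj = -(gi + gk)
    return theta, gi, gj, gk


def dihedrals_and_grads(X, idx):
    """Dihedrals (rad) for quadruples (p1..p4) and per-atom gradients."""
    p1, p2, p3, p4 = idx[:, 0], idx[:, 1], idx[:, 2], idx[:, 3]
    b1 = X[p2] - X[p1]
    b2 = X[p3] - X[p2]
    b3 = X[p4] - X[p3]
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    nb2 = np.sqrt(np.einsum("ij,ij->i", b2, b2))
    m1 = _cross(n1, b2 / nb2[:, None])
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(m1 * n2, axis=1)
    phi = np.arctan2(y, x)
    sn1 = np.sum(n1 * n1, axis=1)
    sn2 = np.sum(n2 * n2, axis=1)
    g1 = (nb2 / sn1)[:, None] * n1
    g4 = -(nb2 / sn2)[:, None] * n2
    A = (np.sum(b1 * b2, axis=1) / nb2 ** 2)[:, None]
    B = (np.sum(b3 * b2, axis=1) / nb2 ** 2)[:, None]
    g2 = -(1.0 + A) * g1 + B * g4
    g3 = A * g1 - (1.0 + B) * g4
    return phi, g1, g2, g3, g4


def _interp_periodic(grid, x_deg):
    """Periodic linear interpolation on a 10-degree grid.

    Returns (value, d value / d x in 1/degree)."""
    n = grid.shape[-1]
    h = 360.0 / n
    s = (np.asarray(x_deg) + 180.0) / h
    i0 = np.floor(s).astype(int) % n
    f = s - np.floor(s)
    i1 = (i0 + 1) % n
    if grid.ndim == 1:
        v0, v1 = grid[i0], grid[i1]
    else:  # rows pre-selected per element
        rows = np.arange(grid.shape[0])
        v0, v1 = grid[rows, i0], grid[rows, i1]
    val = (1.0 - f) * v0 + f * v1
    dval = (v1 - v0) / h
    return val, dval


# --------------------------------------------------------------------------
# topology
# --------------------------------------------------------------------------

class _Topology:
    """Static bonded topology and nonbonded pair bookkeeping."""

    def __init__(self, structure: ComplexStructure, ff: prm.ForceFieldTable):
        n = structure.n_atoms
        key_of = {}
        for i in range(n):
            key_of[i] = (structure.chain_ids[structure.chain_index[i]],
                         int(structure.res_index[i]), structure.atom_name[i])
        bonds = []          # (i, j, r0)
        residues = list(structure.residues())
        res_atoms = {}
        for cid, ri, rn, sel in residues:
            res_atoms[(cid, ri)] = {structure.atom_name[i]: i for i in sel}
        for cid, ri, rn, sel in residues:
            amap = res_atoms[(cid, ri)]
            ideal = chem.ideal_bond_lengths(rn)
            for (a, b) in chem.residue_bonds(rn):
                if a in amap and b in amap:
                    r0 = ideal.get((a, b)) or ideal.get((b, a))
                    bonds.append((amap[a], amap[b], float(r0)))
            nxt = res_atoms.get((cid, ri + 1))
            if nxt and "C" in amap and "N" in nxt:
                bonds.append((amap["C"], nxt["N"], chem.BB_GEOM["C_N"]))
        self.bond_idx = np.array([[i, j] for i, j, _ in bonds], dtype=int
                                 ).reshape(-1, 2)
        self.bond_r0 = np.array([r for _, _, r in bonds])

        # adjacency for angles and exclusions
        adj: dict[int, set] = {i: set() for i in range(n)}
        for i, j, _ in bonds:
            adj[i].add(j)
            adj[j].add(i)
        self.adjacency = adj

        angles = []
        peptide = {
            ("CA", "C", "N"): chem.BB_GEOM["ang_CA_C_N"],
            ("O", "C", "N"): chem.BB_GEOM["ang_O_C_N"],
            ("C", "N", "CA"): chem.BB_GEOM["ang_C_N_CA"],
        }
        for j in range(n):
            nbrs = sorted(adj[j])
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    i, k = nbrs[a], nbrs[b]
                    ki, kj, kk = key_of[i], key_of[j], key_of[k]
                    theta0 = None
                    if ki[:2] == kj[:2] == kk[:2]:
                        ideal = chem.ideal_angles(structure.res_name[j])
                        theta0 = (ideal.get((ki[2], kj[2], kk[2]))
                                  or ideal.get((kk[2], kj[2], ki[2])))
                    if theta0 is None:
                        names = (ki[2], kj[2], kk[2])
                        theta0 = (peptide.get(names)
                                  or peptide.get(names[::-1]))
                    if theta0 is None:
                        theta0 = 115.0  # generic fallback (rare triplets)
                    angles.append((i, j, k, np.radians(theta0)))
        self.angle_idx = np.array([[i, j, k] for i, j, k, _ in angles],
                                  dtype=int).reshape(-1, 3)
        self.angle_t0 = np.array([t for *_ijk, t in angles])

        # exclusion levels: 1-2 and 1-3 excluded, 1-4 scaled
        excl12_13 = set()
        scaled14 = set()
        for i in range(n):
            for j in adj[i]:
                excl12_13.add((min(i, j), max(i, j)))
                for k in adj[j]:
                    if k != i:
                        excl12_13.add((min(i, k), max(i, k)))
                        for l in adj[k]:
                            if l not in (i, j):
                                scaled14.add((min(i, l), max(i, l)))
        scaled14 -= excl12_13
        self.excluded_pairs = excl12_13
        self.scaled14_pairs = scaled14

        # nonbonded pair arrays (upper triangle minus exclusions)
        iu, ju = np.triu_indices(n, 1)
        flat = iu * n + ju
        excl_flat = np.fromiter((i * n + j for i, j in excl12_13), dtype=int,
                                count=len(excl12_13))
        keep = ~np.isin(flat, excl_flat)
        iu, ju = iu[keep], ju[keep]
        s14_flat = np.fromiter((i * n + j for i, j in scaled14), dtype=int,
                               count=len(scaled14))
        coeff = np.where(np.isin(iu * n + ju, s14_flat), SCALE_14, 1.0)
        self.pair_i, self.pair_j, self.pair_coeff = iu, ju, coeff


class EnergyModel:
    """Evaluates the total refinement energy and its gradient.

    Build once per structure topology; evaluate with any coordinate array
    of matching shape (the sampling loops do exactly that).
    """

    def __init__(self, structure: ComplexStructure,
                 restraints: RestraintSet | None = None,
                 weights: EnergyWeights | None = None,
                 ff: prm.ForceFieldTable | None = None,
                 tables: prm.StatTables | None = None,
                 vdw_scale: float = 1.0):
        if not 0.0 < vdw_scale <= 1.0:
            raise ValueError("vdw_scale must be in (0, 1]")
        self.structure = structure
        self.ff = ff or load_default_forcefield()
        if structure.charge is None:
            prm.apply_forcefield(structure, self.ff)
        self.tables = tables or load_default_tables()
        self.weights = (weights or EnergyWeights()).validate()
        self.vdw_scale = float(vdw_scale)
        self.topology = _Topology(structure, self.ff)
        self._setup_nonbonded()
        self._setup_hbond()
        self._setup_torsion_terms()
        self._setup_pairstat()
        self._setup_restraints(restraints)

    # -- static setup -------------------------------------------------------
    def _setup_nonbonded(self):
        st, top = self.structure, self.topology
        i, j = top.pair_i, top.pair_j
        self._rmin = st.radius[i] + st.radius[j]
        self._eps = np.sqrt(st.epsilon[i] * st.epsilon[j])
        self._qq = st.charge[i] * st.charge[j] * COULOMB_K
        elem = np.array(st.element)
        hydrophobic = np.isin(elem, ("C", "S"))
        self._np_mask = hydrophobic[i] & hydrophobic[j]
        self._np_rc = self._rmin + NONPOLAR_PAD

    def _setup_hbond(self):
        st = self.structure
        donors, acceptors = [], []
        for cid, ri, rn, sel in st.residues():
            amap = {st.atom_name[k]: k for k in sel}
            if rn != "PRO" and "N" in amap:
                donors.append((st.chain_index[amap["N"]], ri, amap["N"]))
            if "O" in amap and "C" in amap:
                acceptors.append((st.chain_index[amap["O"]], ri,
                                  amap["O"], amap["C"]))
        pairs = []
        for dc, dr, dn in donors:
            for ac, ar, ao, acb in acceptors:
                if dc == ac and abs(dr - ar) < 2:
                    continue
                pairs.append((dn, ao, acb))
        self._hb = (np.array(pairs, dtype=int).reshape(-1, 3))

    def _setup_torsion_terms(self):
        st = self.structure
        phi_quads, psi_quads = [], []
        chi_quads, chi_rows = [], []
        res_by_key = {}
        for cid, ri, rn, sel in st.residues():
            res_by_key[(cid, ri)] = (rn, {st.atom_name[k]: k for k in sel})
        for (cid, ri), (rn, amap) in res_by_key.items():
            prev = res_by_key.get((cid, ri - 1))
            nxt = res_by_key.get((cid, ri + 1))
            if (prev and nxt and "C" in prev[1] and "N" in nxt[1]
                    and all(a in amap for a in ("N", "CA", "C"))):
                phi_quads.append((prev[1]["C"], amap["N"], amap["CA"],
                                  amap["C"]))
                psi_quads.append((amap["N"], amap["CA"], amap["C"],
                                  nxt[1]["N"]))
            for k, quad in enumerate(chem.CHI_ATOMS[rn], start=1):
                if all(a in amap for a in quad):
                    chi_quads.append(tuple(amap[a] for a in quad))
                    chi_rows.append(self.tables.rotamer[(rn, k)])
        self._phi = np.array(phi_quads, dtype=int).reshape(-1, 4)
        self._psi = np.array(psi_quads, dtype=int).reshape(-1, 4)
        self._chi = np.array(chi_quads, dtype=int).reshape(-1, 4)
        self._chi_grids = (np.vstack(chi_rows) if chi_rows
                           else np.zeros((0, prm.N_GRID)))

    def _setup_pairstat(self):
        st = self.structure
        code = {rt: k for k, rt in enumerate(chem.AA3)}
        reps, types, chains, resis = [], [], [], []
        for cid, ri, rn, sel in st.residues():
            amap = {st.atom_name[k]: k for k in sel}
            rep = amap.get("CB", amap.get("CA"))
            if rep is None:
                continue
            reps.append(rep)
            types.append(code[rn])
            chains.append(st.chain_index[rep])
            resis.append(ri)
        pairs = []
        for a in range(len(reps)):
            for b in range(a + 1, len(reps)):
                if chains[a] == chains[b] and abs(resis[a] - resis[b]) <= 1:
                    continue
                pairs.append((reps[a], reps[b], types[a], types[b]))
        arr = np.array(pairs, dtype=int).reshape(-1, 4)
        self._ps_i, self._ps_j = arr[:, 0], arr[:, 1]
        self._ps_rows = self.tables.pairstat[arr[:, 2], arr[:, 3], :]

    def _setup_restraints(self, restraints: RestraintSet | None):
        st = self.structure
        self.restraints = restraints
        if restraints is None:
            self._dr = None
            self._pr = None
            return
        if restraints.distance:
            di = np.array([resolve_atom(st, r.atom_i)
                           for r in restraints.distance])
            dj = np.array([resolve_atom(st, r.atom_j)
                           for r in restraints.distance])
            d0 = np.array([r.d0 for r in restraints.distance])
            dw = np.array([r.weight for r in restraints.distance])
            self._dr = (di, dj, d0, dw)
        else:
            self._dr = None
        if restraints.position:
            pi = np.array([resolve_atom(st, r.atom_i)
                           for r in restraints.position])
            p0 = np.vstack([r.r0 for r in restraints.position])
            pw = np.array([r.weight for r in restraints.position])
            self._pr = (pi, p0, pw)
        else:
            self._pr = None

    # -- evaluation ---------------------------------------------------------
    def evaluate(self, coords: np.ndarray | None = None):
        """Return (EnergyBreakdown, gradient array (n_atoms, 3))."""
        X = self.structure.coords if coords is None else np.asarray(coords)
        w = self.weights
        n = self.structure.n_atoms
        g = np.zeros((n, 3))
        terms = dict.fromkeys(TERM_NAMES, 0.0)

        top = self.topology
        within = None
        dvec_all = X[top.pair_i] - X[top.pair_j]
        r_all = np.sqrt(np.einsum("ij,ij->i", dvec_all, dvec_all))
        within = r_all < NB_CUTOFF
        ii, jj = top.pair_i[within], top.pair_j[within]
        coeff = top.pair_coeff[within]
        dvec = dvec_all[within]
        r = r_all[within]
        dEdr_sum = np.zeros_like(r)   # weighted sum over all pair terms

        if w.vdw > 0:
            rm = self._rmin[within] * self.vdw_scale
            x6 = (rm / r) ** 6
            e = self._eps[within] * coeff
            terms["vdw"] = float(np.sum(e * (x6 * x6 - 2.0 * x6)))
            dEdr_sum += w.vdw * e * 12.0 * (x6 - x6 * x6) / r
        if w.coulomb > 0 or w.solv_polar > 0:
            qc = self._qq[within] * coeff
            if w.coulomb > 0:
                terms["coulomb"] = float(np.sum(qc / r))
                dEdr_sum += w.coulomb * (-qc / r ** 2)
            if w.solv_polar > 0:
                terms["solv_polar"] = float(
                    np.sum(qc * (0.25 / r ** 2 - 1.0 / r)))
                dEdr_sum += w.solv_polar * qc * (-0.5 / r ** 3 + 1.0 / r ** 2)
        if w.solv_nonpolar > 0:
            rc = self._np_rc[within]
            sel = self._np_mask[within] & (r < rc)
            rs, rcs, cfs = r[sel], rc[sel], coeff[sel]
            u = 1.0 - (rs / rcs) ** 2
            terms["solv_nonpolar"] = float(
                NONPOLAR_GAMMA * np.sum(cfs * u ** 2))
            dd = np.zeros_like(r)
            dd[sel] = (w.solv_nonpolar * NONPOLAR_GAMMA * cfs
                       * (-4.0) * u * rs / rcs ** 2)
            dEdr_sum += dd
        c = (dEdr_sum / r)[:, None] * dvec
        _scatter_add(g, ii, c)
        _scatter_add(g, jj, -c)

        if w.bonded > 0:
            bi, bj = top.bond_idx[:, 0], top.bond_idx[:, 1]
            bv = X[bi] - X[bj]
            br = np.sqrt(np.einsum("ij,ij->i", bv, bv))
            delta = br - top.bond_r0
            e_bond = self.ff.k_bond * np.sum(delta ** 2)
            c = (w.bonded * 2.0 * self.ff.k_bond * delta / br)[:, None] * bv
            _scatter_add(g, bi, c)
            _scatter_add(g, bj, -c)
            theta, gi, gj, gk = angles_and_grads(X, top.angle_idx)
            dtheta = theta - top.angle_t0
            e_ang = self.ff.k_angle * np.sum(dtheta ** 2)
            fac = (w.bonded * 2.0 * self.ff.k_angle * dtheta)[:, None]
            _scatter_add(g, top.angle_idx[:, 0], fac * gi)
            _scatter_add(g, top.angle_idx[:, 1], fac * gj)
            _scatter_add(g, top.angle_idx[:, 2], fac * gk)
            terms["bonded"] = float(e_bond + e_ang)

        if w.hbond > 0 and len(self._hb):
            terms["hbond"] = self._eval_hbond(X, g, w.hbond)

        if w.pairstat > 0 and len(self._ps_i):
            dv = X[self._ps_i] - X[self._ps_j]
            rr = np.sqrt(np.einsum("ij,ij->i", dv, dv))
            val, dval = self._interp_bins(rr)
            terms["pairstat"] = float(np.sum(val))
            c = (w.pairstat * dval / rr)[:, None] * dv
            _scatter_add(g, self._ps_i, c)
            _scatter_add(g, self._ps_j, -c)

        if w.rama > 0 and len(self._phi):
            terms["rama"] = self._eval_rama(X, g, w.rama)

        if w.rotamer > 0 and len(self._chi):
            ang, g1, g2, g3, g4 = dihedrals_and_grads(X, self._chi)
            deg = np.degrees(ang)
            val, dval = _interp_periodic(self._chi_grids, deg)
            terms["rotamer"] = float(np.sum(val))
            fac = (w.rotamer * dval * 180.0 / np.pi)[:, None]
            for col, gg in enumerate((g1, g2, g3, g4)):
                _scatter_add(g, self._chi[:, col], fac * gg)

        if self._dr is not None and w.restraint_distance > 0:
            di, dj, d0, dw = self._dr
            dv = X[di] - X[dj]
            # norm (not einsum) so that reference = input gives exactly 0
            rr = np.linalg.norm(dv, axis=1)
            delta = rr - d0
            terms["restraint_distance"] = float(np.sum(dw * delta ** 2))
            c = (w.restraint_distance * 2.0 * dw * delta / rr)[:, None] * dv
            _scatter_add(g, di, c)
            _scatter_add(g, dj, -c)
        if self._pr is not None and w.restraint_position > 0:
            ri, r0, rw = self._pr
            dv = X[ri] - r0
            terms["restraint_position"] = float(
                np.sum(rw * np.sum(dv ** 2, axis=1)))
            _scatter_add(g, ri, w.restraint_position * 2.0 * rw[:, None] * dv)

        total = float(sum(terms[t] * getattr(w, t) for t in TERM_NAMES))
        return EnergyBreakdown(terms=terms, weights=w, total=total), g

    def _interp_bins(self, r):
        """Linear interpolation in the pair-potential distance bins."""
        nbins = self._ps_rows.shape[1]
        s = r / prm.PAIRSTAT_BIN - 0.5
        s = np.clip(s, 0.0, nbins - 1.0 - 1e-12)
        i0 = np.floor(s).astype(int)
        f = s - i0
        rows = np.arange(self._ps_rows.shape[0])
        v0 = self._ps_rows[rows, i0]
        v1 = self._ps_rows[rows, np.minimum(i0 + 1, nbins - 1)]
        val = (1 - f) * v0 + f * v1
        dval = (v1 - v0) / prm.PAIRSTAT_BIN
        # outside the table (clamped) the potential is flat
        dval[(r / prm.PAIRSTAT_BIN - 0.5 < 0)
             | (r / prm.PAIRSTAT_BIN - 0.5 > nbins - 1)] = 0.0
        return val, dval

    def _eval_hbond(self, X, g, weight):
        dn, ao, ac = self._hb[:, 0], self._hb[:, 1], self._hb[:, 2]
        dv = X[dn] - X[ao]
        r = np.linalg.norm(dv, axis=1)
        active = (r > HBOND_DMIN) & (r < HBOND_DMAX)
        if not np.any(active):
            return 0.0
        dn, ao, ac, dv, r = dn[active], ao[active], ac[active], dv[active], \
            r[active]
        u = np.pi * (r - HBOND_DMIN) / (HBOND_DMAX - HBOND_DMIN)
        fd = np.sin(u) ** 2
        dfd = (2.0 * np.sin(u) * np.cos(u)
               * np.pi / (HBOND_DMAX - HBOND_DMIN))
        trip = np.stack([ac, ao, dn], axis=1)
        theta, gi, gj, gk = angles_and_grads(X, trip)
        tdeg = np.degrees(theta)
        v = np.pi * (tdeg - HBOND_AMIN_DEG) / HBOND_ARANGE_DEG
        inwin = (tdeg > HBOND_AMIN_DEG) & (tdeg < HBOND_AMIN_DEG
                                           + HBOND_ARANGE_DEG)
        fa = np.where(inwin, np.sin(np.clip(v, 0, np.pi)) ** 2, 0.0)
        dfa_dtheta = np.where(
            inwin,
            2.0 * np.sin(v) * np.cos(v) * np.pi / np.radians(
                HBOND_ARANGE_DEG),
            0.0)  # per radian of theta
        e = -HBOND_STRENGTH * float(np.sum(fd * fa))
        # distance part
        dEdr = -HBOND_STRENGTH * dfd * fa
        c = (weight * dEdr / r)[:, None] * dv
        _scatter_add(g, dn, c)
        _scatter_add(g, ao, -c)
        # angle part
        fac = (-weight * HBOND_STRENGTH * fd * dfa_dtheta)[:, None]
        _scatter_add(g, ac, fac * gi)
        _scatter_add(g, ao, fac * gj)
        _scatter_add(g, dn, fac * gk)
        return e

    def _eval_rama(self, X, g, weight):
        total = 0.0
        phi, p1, p2, p3, p4 = dihedrals_and_grads(X, self._phi)
        psi, q1, q2, q3, q4 = dihedrals_and_grads(X, self._psi)
        phi_d = np.degrees(phi)
        psi_d = np.degrees(psi)
        n = prm.N_GRID
        h = 360.0 / n
        sp = (phi_d + 180.0) / h
        sq = (psi_d + 180.0) / h
        i0 = np.floor(sp).astype(int) % n
        j0 = np.floor(sq).astype(int) % n
        fp = sp - np.floor(sp)
        fq = sq - np.floor(sq)
        i1, j1 = (i0 + 1) % n, (j0 + 1) % n
        R = self.tables.rama
        v00, v01 = R[i0, j0], R[i0, j1]
        v10, v11 = R[i1, j0], R[i1, j1]
        val = (v00 * (1 - fp) * (1 - fq) + v10 * fp * (1 - fq)
               + v01 * (1 - fp) * fq + v11 * fp * fq)
        total = float(np.sum(val))
        dphi = ((v10 - v00) * (1 - fq) + (v11 - v01) * fq) / h  # per degree
        dpsi = ((v01 - v00) * (1 - fp) + (v11 - v10) * fp) / h
        facp = (dphi * 180.0 / np.pi)[:, None]
        facq = (dpsi * 180.0 / np.pi)[:, None]
        for col, gg in enumerate((p1, p2, p3, p4)):
            _scatter_add(g, self._phi[:, col], weight * facp * gg)
        for col, gg in enumerate((q1, q2, q3, q4)):
            _scatter_add(g, self._psi[:, col], weight * facq * gg)
        return total

    def energy_total(self, coords=None) -> float:
        breakdown, _ = self.evaluate(coords)
        return breakdown.total

    # -- clash detection ----------------------------------------------------
    def clash_free(self, coords, residues, vdw_scale: float = 0.7,
                   overlap_factor: float = CLASH_OVERLAP_FACTOR) -> bool:
        """True iff no side-chain atom of *residues* overlaps any atom.

        Overlap: distance strictly below
        overlap_factor * (r_i + r_j) * vdw_scale, 1-2/1-3 pairs excluded.
        """
        st = self.structure
        sc = []
        for (cid, ri) in residues:
            ci = st.chain_ids.index(cid)
            sel = np.nonzero((st.chain_index == ci) & (st.res_index == ri))[0]
            sc.extend(i for i in sel
                      if st.atom_name[i] not in chem.BACKBONE_ATOMS)
        if not sc:
            return True
        sc = np.array(sc, dtype=int)
        X = np.asarray(coords)
        d = np.linalg.norm(X[sc][:, None, :] - X[None, :, :], axis=2)
        limit = (st.radius[sc][:, None] + st.radius[None, :]) \
            * vdw_scale * overlap_factor
        close = d < limit
        excl = self.topology.excluded_pairs
        for a, i in enumerate(sc):
            close[a, i] = False
            for j in np.nonzero(close[a])[0]:
                if (min(i, j), max(i, j)) in excl:
                    close[a, j] = False
        return not bool(close.any())


# --------------------------------------------------------------------------
# module-level convenience API
# --------------------------------------------------------------------------

_DEFAULT_FF = None
_DEFAULT_TABLES = None


def load_default_forcefield() -> prm.ForceFieldTable:
    global _DEFAULT_FF
    if _DEFAULT_FF is None:
        _DEFAULT_FF = prm.load_forcefield()
    return _DEFAULT_FF


def load_default_tables() -> prm.StatTables:
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = prm.default_tables()
    return _DEFAULT_TABLES


def total_energy(structure: ComplexStructure,
                 restraints: RestraintSet | None = None,
                 weights: EnergyWeights | None = None,
                 vdw_scale: float = 1.0, **kw) -> EnergyBreakdown:
    model = EnergyModel(structure, restraints, weights,
                        vdw_scale=vdw_scale, **kw)
    breakdown, _ = model.evaluate()
    if not np.isfinite(breakdown.total):
        raise NonFiniteEnergy("total energy is not finite")
    return breakdown


def gradient(structure: ComplexStructure,
             restraints: RestraintSet | None = None,
             weights: EnergyWeights | None = None,
             vdw_scale: float = 1.0, **kw) -> np.ndarray:
    model = EnergyModel(structure, restraints, weights,
                        vdw_scale=vdw_scale, **kw)
    _, g = model.evaluate()
    return g


def restraint_energy(structure: ComplexStructure, restraints: RestraintSet):
    """(distance term, position term) with unit global weights."""
    from .restraints import pair_distance
    X = structure.coords
    dist = 0.0
    for rtr in restraints.distance:
        i = resolve_atom(structure, rtr.atom_i)
        j = resolve_atom(structure, rtr.atom_j)
        d = pair_distance(X[i], X[j])
        dist += rtr.weight * (d - rtr.d0) ** 2
    pos = 0.0
    for rtr in restraints.position:
        i = resolve_atom(structure, rtr.atom_i)
        pos += rtr.weight * float(np.sum((X[i] - rtr.r0) ** 2))
    return dist, pos


def clash_check(structure: ComplexStructure, residues,
                vdw_scale: float = 0.7,
                overlap_factor: float = CLASH_OVERLAP_FACTOR,
                model: EnergyModel | None = None) -> bool:
    """True iff the listed residues' side chains are clash-free."""
    if model is None:
        model = EnergyModel(structure)
    return model.clash_free(structure.coords, residues, vdw_scale,
                            overlap_factor)
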