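"""Amino-acid chemistry: ideal geometry, side-chain templates and topology.

Residue side chains are described by small internal-coordinate templates
(one entry per heavy atom: bond length, bond angle, dihedral).  Rotatable
chi dihedrals enter the templates symbolically, so a side chain can be
rebuilt for any rotamer with bond lengths and angles unchanged.  The same
tables drive the synthetic-fixture builder, the rotamer repacking moves and
the equilibrium values of the bonded energy term, which keeps the model
self-consistent: an ideally built structure has (near-)zero bonded strain.

All distances are in Angstrom, all angles in degrees at the API surface.
"""
from __future__ import annotations

from functools import lru_cache
from math import cos, radians, sin

import numpy as np

AA3 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# ideal backbone internal coordinates (consistent between the helix builder
# and the bonded-term equilibria)
BB_GEOM = {
    "N_CA": 1.458,
    "CA_C": 1.525,
    "C_O": 1.231,
    "C_N": 1.329,           # peptide bond
    "ang_N_CA_C": 111.2,
    "ang_CA_C_O": 120.8,
    "ang_CA_C_N": 116.2,
    "ang_O_C_N": 123.0,
    "ang_C_N_CA": 121.7,
    "omega": 180.0,
    # CB stub: bond CA-CB, angle N-CA-CB, improper dihedral C-N-CA-CB
    "CA_CB": 1.530,
    "ang_N_CA_CB": 110.5,
    "dih_C_N_CA_CB": -122.6,
}

# --------------------------------------------------------------------------
# geometry primitives
# --------------------------------------------------------------------------

def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """NeRF placement: return x bonded to c with angle(b,c,x)=angle and
    dihedral(a,b,c,x)=dihedral."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    ang = radians(angle_deg)
    dih = radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("collinear reference atoms in place_atom")
    n = n / nn
    m = np.cross(n, bc)
    d = np.array([
        -bond * cos(ang),
        bond * sin(ang) * cos(dih),
        -bond * sin(ang) * sin(dih),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def measure_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 in degrees."""
    u = np.asarray(p1, float) - np.asarray(p2, float)
    v = np.asarray(p3, float) - np.asarray(p2, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral p1-p2-p3-p4 in degrees, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


# --------------------------------------------------------------------------
# side-chain templates
# --------------------------------------------------------------------------
# Template entry: (atom_name, element, (a, b, c) reference atoms,
#                  bond length to c, angle b-c-x, dihedral spec).
# Dihedral spec: ("fix", value) or ("chi", k, offset) meaning chi_k + offset.
# The new atom is covalently bonded to reference atom c.

def _chi(k, off=0.0):
    return ("chi", k, off)


def _fx(v):
    return ("fix", v)


SIDECHAIN_TEMPLATES: dict[str, list] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, _chi(1))],
    "CYS": [("SG", "S", ("N", "CA", "CB"), 1.808, 113.8, _chi(1))],
    "THR": [("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, _chi(1)),
            ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -120.0))],
    "VAL": [("CG1", "C", ("N", "CA", "CB"), 1.527, 110.7, _chi(1)),
            ("CG2", "C", ("N", "CA", "CB"), 1.527, 110.4, _chi(1, 122.3))],
    "ILE": [("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, _chi(1)),
            ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -122.3)),
            ("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.8, _chi(2))],
    "LEU": [("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, _chi(1)),
            ("CD1", "C", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2)),
            ("CD2", "C", ("CA", "CB", "CG"), 1.521, 110.4, _chi(2, 122.6))],
    "PRO": [("CG", "C", ("N", "CA", "CB"), 1.495, 104.5, _fx(31.6)),
            ("CD", "C", ("CA", "CB", "CG"), 1.507, 106.1, _fx(-34.9))],
    "MET": [("CG", "C", ("N", "CA", "CB"), 1.535, 114.1, _chi(1)),
            ("SD", "S", ("CA", "CB", "CG"), 1.807, 112.7, _chi(2)),
            ("CE", "C", ("CB", "CG", "SD"), 1.789, 100.9, _chi(3))],
    "ASP": [("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
            ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.5, _chi(2)),
            ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.5, _chi(2, 180.0))],
    "ASN": [("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
            ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, _chi(2)),
            ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, _chi(2, 180.0))],
    "GLU": [("CG", "C", ("N", "CA", "CB"), 1.530, 114.1, _chi(1)),
            ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
            ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.5, _chi(3)),
            ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.5, _chi(3, 180.0))],
    "GLN": [("CG", "C", ("N", "CA", "CB"), 1.530, 114.1, _chi(1)),
            ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
            ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, _chi(3)),
            ("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, _chi(3, 180.0))],
    "LYS": [("CG", "C", ("N", "CA", "CB"), 1.530, 114.1, _chi(1)),
            ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
            ("CE", "C", ("CB", "CG", "CD"), 1.508, 111.3, _chi(3)),
            ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.9, _chi(4))],
    "ARG": [("CG", "C", ("N", "CA", "CB"), 1.530, 114.1, _chi(1)),
            ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
            ("NE", "N", ("CB", "CG", "CD"), 1.461, 112.0, _chi(3)),
            ("CZ", "C", ("CG", "CD", "NE"), 1.329, 124.2, _chi(4)),
            ("NH1", "N", ("CD", "NE", "CZ"), 1.326, 120.0, _fx(0.0)),
            ("NH2", "N", ("CD", "NE", "CZ"), 1.326, 120.0, _fx(180.0))],
    "PHE": [("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
            ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2)),
            ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2, 180.0)),
            ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 120.8, _fx(180.0)),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 120.8, _fx(180.0)),
            ("CZ", "C", ("CG", "CD1", "CE1"), 1.382, 120.0, _fx(0.0))],
    "TYR": [("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
            ("CD1", "C", ("CA", "CB", "CG"), 1.389, 120.8, _chi(2)),
            ("CD2", "C", ("CA", "CB", "CG"), 1.389, 120.8, _chi(2, 180.0)),
            ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 121.1, _fx(180.0)),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 121.1, _fx(180.0)),
            ("CZ", "C", ("CG", "CD1", "CE1"), 1.378, 119.5, _fx(0.0)),
            ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 119.9, _fx(180.0))],
    "HIS": [("CG", "C", ("N", "CA", "CB"), 1.497, 113.8, _chi(1)),
            ("ND1", "N", ("CA", "CB", "CG"), 1.371, 122.7, _chi(2)),
            ("CD2", "C", ("CA", "CB", "CG"), 1.356, 131.2, _chi(2, 180.0)),
            ("CE1", "C", ("CB", "CG", "ND1"), 1.319, 109.0, _fx(180.0)),
            ("NE2", "N", ("CB", "CG", "CD2"), 1.374, 107.2, _fx(180.0))],
    "TRP": [("CG", "C", ("N", "CA", "CB"), 1.498, 113.6, _chi(1)),
            ("CD1", "C", ("CA", "CB", "CG"), 1.363, 126.9, _chi(2)),
            ("CD2", "C", ("CA", "CB", "CG"), 1.433, 126.6, _chi(2, 180.0)),
            ("NE1", "N", ("CB", "CG", "CD1"), 1.375, 110.2, _fx(180.0)),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.409, 107.2, _fx(180.0)),
            ("CE3", "C", ("CB", "CG", "CD2"), 1.400, 133.9, _fx(0.0)),
            ("CZ2", "C", ("CG", "CD2", "CE2"), 1.394, 122.4, _fx(180.0)),
            ("CZ3", "C", ("CG", "CD2", "CE3"), 1.382, 118.6, _fx(180.0)),
            ("CH2", "C", ("CD2", "CE2", "CZ2"), 1.368, 117.5, _fx(0.0))],
}

# ring-closure bonds that the sequential templates cannot express
CLOSURE_BONDS: dict[str, list[tuple[str, str]]] = {
    "PHE": [("CZ", "CE2")],
    "TYR": [("CZ", "CE2")],
    "HIS": [("CE1", "NE2")],
    "TRP": [("NE1", "CE2"), ("CZ3", "CH2")],
    "PRO": [("CD", "N")],
}

# chi dihedral atom quadruples (matching the template chi definitions)
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ALA": [], "GLY": [], "PRO": [],
}


def n_chi(restype: str) -> int:
    return len(CHI_ATOMS[restype])


def has_cb(restype: str) -> bool:
    return restype != "GLY"


def residue_atom_names(restype: str) -> list[str]:
    """Canonical heavy-atom ordering: backbone, then CB, then template order."""
    names = list(BACKBONE_ATOMS)
    if has_cb(restype):
        names.append("CB")
    names.extend(e[0] for e in SIDECHAIN_TEMPLATES[restype])
    return names


def atom_element(restype: str, atom_name: str) -> str:
    if atom_name in ("N",):
        return "N"
    if atom_name in ("O",):
        return "O"
    if atom_name in ("CA", "C", "CB"):
        return "C"
    for name, elem, *_ in SIDECHAIN_TEMPLATES[restype]:
        if name == atom_name:
            return elem
    raise KeyError(f"unknown atom {atom_name} for {restype}")


def build_cb(n, ca, c):
    """Place CB from the three backbone atoms (fixed L-configuration)."""
    return place_atom(c, n, ca, BB_GEOM["CA_CB"], BB_GEOM["ang_N_CA_CB"],
                      BB_GEOM["dih_C_N_CA_CB"])


def build_sidechain(restype: str, backbone: dict, chis=()) -> dict:
    """Build side-chain heavy atoms from backbone N/CA/C coordinates.

    Parameters
    ----------
    backbone : dict mapping "N","CA","C" (at least) to 3-vectors.
    chis : sequence of chi angles in degrees; missing values default to 0.

    Returns a dict atom_name -> coordinates including CB (empty for GLY).
    """
    out: dict = {}
    pos = dict(backbone)
    if not has_cb(restype):
        return out
    cb = build_cb(pos["N"], pos["CA"], pos["C"])
    out["CB"] = cb
    pos["CB"] = cb
    chis = list(chis)
    for name, _elem, refs, bond, ang, dspec in SIDECHAIN_TEMPLATES[restype]:
        if dspec[0] == "fix":
            dval = dspec[1]
        else:
            _, k, off = dspec
            base = chis[k - 1] if k - 1 < len(chis) else 0.0
            dval = base + off
        a, b, c = (pos[r] for r in refs)
        xyz = place_atom(a, b, c, bond, ang, dval)
        out[name] = xyz
        pos[name] = xyz
    return out


def measure_chis(restype: str, coords: dict) -> list[float]:
    """Measure the chi dihedrals of a residue from its atom coordinates."""
    vals = []
    for quad in CHI_ATOMS[restype]:
        vals.append(measure_dihedral(*(coords[a] for a in quad)))
    return vals


# --------------------------------------------------------------------------
# intra-residue topology and ideal equilibrium geometry
# --------------------------------------------------------------------------

def residue_bonds(restype: str) -> list[tuple[str, str]]:
    """Covalent heavy-atom bonds within one residue (peptide C-N excluded,
    except the PRO ring-closure CD-N)."""
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    if has_cb(restype):
        bonds.append(("CA", "CB"))
    for name, _e, refs, *_ in SIDECHAIN_TEMPLATES[restype]:
        bonds.append((refs[2], name))
    bonds.extend(CLOSURE_BONDS.get(restype, []))
    return bonds


@lru_cache(maxsize=None)
def ideal_residue_geometry(restype: str) -> dict:
    """Coordinates of an isolated, ideally built residue (chi = 0).

    Used only to measure equilibrium bond lengths/angles; these do not
    depend on the chi values because the templates fix bonds and angles.
    """
    n = np.zeros(3)
    ca = np.array([BB_GEOM["N_CA"], 0.0, 0.0])
    th = radians(180.0 - BB_GEOM["ang_N_CA_C"])
    c = ca + BB_GEOM["CA_C"] * np.array([cos(th), sin(th), 0.0])
    o = place_atom(n, ca, c, BB_GEOM["C_O"], BB_GEOM["ang_CA_C_O"], -47.0 + 180.0)
    pos = {"N": n, "CA": ca, "C": c, "O": o}
    pos.update(build_sidechain(restype, pos))
    return pos


@lru_cache(maxsize=None)
def ideal_bond_lengths(restype: str) -> dict:
    geom = ideal_residue_geometry(restype)
    out = {}
    for a, b in residue_bonds(restype):
        if a in geom and b in geom:
            out[(a, b)] = float(np.linalg.norm(geom[a] - geom[b]))
    return out


@lru_cache(maxsize=None)
def ideal_angles(restype: str) -> dict:
    """Equilibrium angles (degrees) for every bonded triplet in the residue."""
    geom = ideal_residue_geometry(restype)
    nbrs: dict[str, list[str]] = {}
    for a, b in residue_bonds(restype):
        if a in geom and b in geom:
            nbrs.setdefault(a, []).append(b)
            nbrs.setdefault(b, []).append(a)
    out = {}
    for j, around in nbrs.items():
        for ii in range(len(around)):
            for kk in range(ii + 1, len(around)):
                i, k = around[ii], around[kk]
                out[(i, j, k)] = measure_angle(geom[i], geom[j], geom[k])
    return out
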