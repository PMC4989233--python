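"""Parameter tables: force field, rotamer library, statistical grids.

The force field is a deliberately simple per-element Lennard-Jones +
per-residue partial-charge table with stiffness-capped bonded constants.
Statistical (knowledge-based) terms use coarse grids: a 10-degree phi/psi
grid, per-chi 10-degree rotamer grids and a residue-pair distance-binned
pair potential (zero by default; synthetic tables are used in tests).
"""
from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import chemistry as chem
from .errors import EmptyLibrary, ParameterMissing

GRID_STEP_DEG = 10.0
N_GRID = 36
PAIRSTAT_BIN = 0.5       # Angstrom
PAIRSTAT_RMAX = 15.0


def _data_path(name: str):
    return resources.files("refinecomplex") / "data" / name


# --------------------------------------------------------------------------
# force field
# --------------------------------------------------------------------------

@dataclass
class ForceFieldTable:
    """Per-element vdW parameters, partial charges and bonded constants."""

    elements: dict                 # element -> (radius, epsilon)
    backbone_charges: dict         # atom name -> charge
    charges: dict                  # (residue, atom) -> charge
    k_bond: float = 100.0
    k_angle: float = 25.0

    def vdw(self, element: str):
        try:
            return self.elements[element]
        except KeyError:
            raise ParameterMissing(f"element {element!r} not in force field")

    def charge(self, residue: str, atom: str) -> float:
        if atom in self.backbone_charges:
            return self.backbone_charges[atom]
        return self.charges.get((residue, atom), 0.0)


def load_forcefield(path=None) -> ForceFieldTable:
    if path is None:
        path = _data_path("forcefield.yaml")
    with open(str(path)) as fh:
        raw = yaml.safe_load(fh)
    elements = {el: (float(v["radius"]), float(v["epsilon"]))
                for el, v in raw["elements"].items()}
    charges = {}
    for res, d in raw.get("charges", {}).items():
        for atom, q in d.items():
            charges[(res, atom)] = float(q)
    return ForceFieldTable(
        elements=elements,
        backbone_charges={k: float(v)
                          for k, v in raw["backbone_charges"].items()},
        charges=charges,
        k_bond=float(raw.get("k_bond", 100.0)),
        k_angle=float(raw.get("k_angle", 25.0)),
    )


def apply_forcefield(structure, ff: ForceFieldTable):
    """Fill the structure's charge/radius/epsilon arrays in place."""
    n = structure.n_atoms
    charge = np.zeros(n)
    radius = np.zeros(n)
    epsilon = np.zeros(n)
    for i in range(n):
        r, e = ff.vdw(structure.element[i])
        radius[i] = r
        epsilon[i] = e
        charge[i] = ff.charge(structure.res_name[i], structure.atom_name[i])
    structure.charge = charge
    structure.radius = radius
    structure.epsilon = epsilon
    return structure


# --------------------------------------------------------------------------
# rotamer library
# --------------------------------------------------------------------------

@dataclass
class RotamerLibrary:
    """Per-residue-type list of (chi tuple in degrees, probability)."""

    rotamers: dict = field(default_factory=dict)

    def get(self, restype: str):
        try:
            rots = self.rotamers[restype]
        except KeyError:
            raise EmptyLibrary(f"no rotamers for residue type {restype}")
        return rots

    def validate(self):
        for rt, rots in self.rotamers.items():
            want = chem.n_chi(rt)
            total = 0.0
            for chis, p in rots:
                if len(chis) != want:
                    raise ValueError(
                        f"{rt}: rotamer has {len(chis)} chi values, "
                        f"expected {want}")
                if not (0.0 < p <= 1.0):
                    raise ValueError(f"{rt}: probability {p} out of (0,1]")
                total += p
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{rt}: probabilities sum to {total}")
        return self


def load_rotamer_library(path=None) -> RotamerLibrary:
    if path is None:
        path = _data_path("rotamers.txt")
    lib: dict = {}
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            rt = parts[0]
            chis = tuple(float(x) for x in parts[1:5] if x != ".")
            prob = float(parts[5])
            lib.setdefault(rt, []).append((chis[:chem.n_chi(rt)], prob))
    return RotamerLibrary(lib).validate()


def save_rotamer_library(lib: RotamerLibrary, path):
    with open(str(path), "w") as fh:
        fh.write("# residue chi1 chi2 chi3 chi4 probability\n")
        for rt in sorted(lib.rotamers):
            for chis, p in lib.rotamers[rt]:
                cols = [f"{c:g}" for c in chis] + ["."] * (4 - len(chis))
                fh.write(f"{rt} {' '.join(cols)} {p:g}\n")


# --------------------------------------------------------------------------
# statistical grids
# --------------------------------------------------------------------------

@dataclass
class StatTables:
    """Knowledge-based grids used by the rama/rotamer/pairstat terms.

    rama : (36, 36) energy grid over (phi, psi), 10-degree spacing,
        grid point k at -180 + 10*k degrees.
    rotamer : dict (residue type, chi index 1-based) -> (36,) energy grid.
    pairstat : (20, 20, nbins) energy table over residue-type pairs and
        Cbeta-Cbeta distance bins of 0.5 A (type order = chemistry.AA3).
    """

    rama: np.ndarray
    rotamer: dict
    pairstat: np.ndarray

    @property
    def pairstat_nbins(self) -> int:
        return self.pairstat.shape[2]


def _periodic_gaussian(centers_deg, width_deg, weights, grid_deg):
    """Sum of periodic Gaussians evaluated on a degree grid."""
    out = np.zeros_like(grid_deg, dtype=float)
    for c, w in zip(centers_deg, weights):
        d = (grid_deg - c + 180.0) % 360.0 - 180.0
        out += w * np.exp(-0.5 * (d / width_deg) ** 2)
    return out


def default_tables(library: RotamerLibrary | None = None) -> StatTables:
    """Mildly informative default grids.

    The phi/psi grid prefers the alpha-helical basin; each chi grid
    prefers the library rotamer values; the pair potential is zero.
    """
    if library is None:
        library = load_rotamer_library()
    grid = -180.0 + GRID_STEP_DEG * np.arange(N_GRID)
    # rama: product of 1-D preferences around the helical basin
    p_phi = 0.25 + _periodic_gaussian([-57.0], 25.0, [1.0], grid)
    p_psi = 0.25 + _periodic_gaussian([-47.0], 25.0, [1.0], grid)
    rama = -np.log(np.outer(p_phi, p_psi))
    rot: dict = {}
    for rt, rots in library.rotamers.items():
        for k in range(1, chem.n_chi(rt) + 1):
            centers = [chis[k - 1] for chis, _p in rots]
            weights = [p for _chis, p in rots]
            p = 0.25 + _periodic_gaussian(centers, 20.0, weights, grid)
            rot[(rt, k)] = -np.log(p)
    nbins = int(round(PAIRSTAT_RMAX / PAIRSTAT_BIN))
    pairstat = np.zeros((len(chem.AA3), len(chem.AA3), nbins))
    return StatTables(rama=rama, rotamer=rot, pairstat=pairstat)
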