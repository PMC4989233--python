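"""Conformational sampling primitives.

Three operations drive the refinement protocol: local energy minimization
(L-BFGS-B on the analytic gradient), short Langevin-dynamics relaxations
(BAOAB splitting) and Metropolis Monte Carlo repacking of interface side
chains from a rotamer library.  All randomness is drawn from explicit
seeds, so every operation is bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial.distance import cdist

from . import chemistry as chem
from .energy import EnergyModel, EnergyWeights
from .errors import NonFiniteEnergy
from .params import RotamerLibrary
from .restraints import InterfaceSet, RestraintSet
from .structure import ComplexStructure, set_sidechain_chis
from .structure_io import SymmetryGroup, enforce_symmetry

KB = 0.0019872041          # kcal/mol/K
ACC_FACTOR = 4.184e-4      # kcal/mol/A -> amu*A/fs^2
ELEMENT_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


@dataclass
class MDParams:
    """Langevin dynamics settings (timestep fs, duration ps, T in K)."""

    timestep_fs: float = 4.0
    duration_ps: float = 0.6
    temperature_K: float = 300.0
    friction: float = 1.0          # 1/ps
    seed: int = 0

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_ps * 1000.0 / self.timestep_fs))


def _model_for(structure, restraints, weights, vdw_scale=1.0, model=None,
               **kw):
    if model is not None:
        return model
    return EnergyModel(structure, restraints, weights, vdw_scale=vdw_scale,
                       **kw)


def minimize(structure: ComplexStructure,
             restraints: RestraintSet | None = None,
             weights: EnergyWeights | None = None,
             max_steps: int = 200, tol: float = 1e-3,
             model: EnergyModel | None = None, **kw) -> ComplexStructure:
    """Local minimization; the returned energy never exceeds the input's."""
    model = _model_for(structure, restraints, weights, model=model, **kw)
    x0 = structure.coords.ravel()
    bd0, _ = model.evaluate(structure.coords)
    if not np.isfinite(bd0.total):
        raise NonFiniteEnergy("input energy is not finite")

    def fun(x):
        bd, g = model.evaluate(x.reshape(-1, 3))
        return bd.total, g.ravel()

    res = scipy_minimize(fun, x0, jac=True, method="L-BFGS-B",
                         options={"maxiter": max_steps, "gtol": tol,
                                  "ftol": 1e-12})
    out = res.x.reshape(-1, 3)
    if res.fun > bd0.total or not np.all(np.isfinite(out)):
        out = structure.coords
    return structure.with_coords(out, provenance=structure.provenance)


def md_relax(structure: ComplexStructure,
             restraints: RestraintSet | None = None,
             weights: EnergyWeights | None = None,
             params: MDParams | None = None,
             symmetry: SymmetryGroup | None = None,
             model: EnergyModel | None = None, **kw) -> ComplexStructure:
    """Langevin relaxation (BAOAB).  With a symmetry group, the structure
    is projected back onto exact Cn symmetry after every step."""
    params = params or MDParams()
    model = _model_for(structure, restraints, weights, model=model, **kw)
    n_steps = params.n_steps
    if n_steps == 0:
        return structure.copy()
    rng = np.random.default_rng(params.seed)
    mass = np.array([ELEMENT_MASS[e] for e in structure.element])[:, None]
    dt = params.timestep_fs
    gamma = params.friction / 1000.0          # 1/fs
    kT = KB * max(params.temperature_K, 0.0)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(1.0 - c1 * c1, 0.0))
    sigma = np.sqrt(kT * ACC_FACTOR / mass)   # A/fs thermal width

    X = structure.coords.copy()
    if kT > 0:
        v = sigma * rng.standard_normal(size=X.shape)
    else:
        v = np.zeros_like(X)

    sym_struct = structure.copy() if symmetry is not None else None

    def force(x):
        _bd, g = model.evaluate(x)
        return -g * ACC_FACTOR / mass   # A/fs^2

    a = force(X)
    for _step in range(n_steps):
        v += 0.5 * dt * a
        X += 0.5 * dt * v
        if kT > 0:
            v = c1 * v + c2 * sigma * rng.standard_normal(size=X.shape)
        else:
            v = c1 * v
        X += 0.5 * dt * v
        if symmetry is not None:
            sym_struct.coords = X
            X = enforce_symmetry(sym_struct, symmetry).coords
        if not np.all(np.isfinite(X)) or np.max(np.abs(X)) > 1e6:
            raise NonFiniteEnergy("MD integration blew up")
        a = force(X)
    return structure.with_coords(X, provenance=structure.provenance)


def kinetic_trace(structure: ComplexStructure, params: MDParams,
                  restraints=None, weights=None,
                  model: EnergyModel | None = None, **kw) -> np.ndarray:
    """Per-step kinetic energy (kcal/mol) of a Langevin run; diagnostics
    for thermostat calibration."""
    model = _model_for(structure, restraints, weights, model=model, **kw)
    rng = np.random.default_rng(params.seed)
    mass = np.array([ELEMENT_MASS[e] for e in structure.element])[:, None]
    dt = params.timestep_fs
    gamma = params.friction / 1000.0
    kT = KB * params.temperature_K
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(1.0 - c1 * c1, 0.0))
    sigma = np.sqrt(kT * ACC_FACTOR / mass)
    X = structure.coords.copy()
    v = sigma * rng.standard_normal(size=X.shape)
    a = -model.evaluate(X)[1] * ACC_FACTOR / mass
    out = []
    for _ in range(params.n_steps):
        v += 0.5 * dt * a
        X += 0.5 * dt * v
        v = c1 * v + c2 * sigma * rng.standard_normal(size=X.shape)
        X += 0.5 * dt * v
        a = -model.evaluate(X)[1] * ACC_FACTOR / mass
        v_mid = v + 0.5 * dt * a
        ke = 0.5 * np.sum(mass * v_mid ** 2) / ACC_FACTOR
        out.append(ke)
    return np.array(out)


# --------------------------------------------------------------------------
# interface side-chain repacking
# --------------------------------------------------------------------------

def select_clusters(interface: InterfaceSet, structure: ComplexStructure,
                    n_clusters: int = 3, max_size: int = 5,
                    seed: int = 0) -> list:
    """Clusters of up to max_size spatially adjacent interfacial residues.

    Each cluster is a distinct randomly drawn seed residue plus its
    max_size-1 nearest interfacial neighbours by CA distance.
    """
    members = interface.sorted_members()
    if not members:
        return []
    rng = np.random.default_rng(seed)
    ca = np.array([structure.coords[structure.atom_index(c, r, "CA")]
                   for c, r in members])
    dist = cdist(ca, ca)
    if len(members) >= n_clusters:
        seeds = rng.choice(len(members), size=n_clusters, replace=False)
    else:
        seeds = rng.choice(len(members), size=n_clusters, replace=True)
    clusters = []
    for s in seeds:
        order = np.argsort(dist[s], kind="stable")
        take = [members[i] for i in order[:max_size]]
        clusters.append(take)
    return clusters


def repack_interface(structure: ComplexStructure, interface: InterfaceSet,
                     library: RotamerLibrary, n_mc_steps: int = 3,
                     n_clusters: int = 3, vdw_scale: float = 0.7,
                     seed: int = 0, temperature_K: float = 300.0,
                     restraints: RestraintSet | None = None,
                     weights: EnergyWeights | None = None,
                     model: EnergyModel | None = None,
                     stats: dict | None = None, **kw) -> ComplexStructure:
    """Metropolis MC repacking of interface side chains.

    For each of n_clusters clusters, n_mc_steps moves are attempted; a
    move proposes library rotamers jointly for the cluster, is rejected
    outright if it clashes at the reduced vdW radii, and otherwise
    accepted by the Metropolis criterion on the total energy (evaluated at
    the same reduced radii).  Backbone and non-interface atoms are
    bit-identical to the input.
    """
    out = structure.copy()
    if len(interface) == 0:
        import logging
        logging.getLogger(__name__).warning(
            "empty interface: repacking is a no-op")
        return out
    model = _model_for(structure, restraints, weights, vdw_scale=vdw_scale,
                       model=model, **kw)
    rng = np.random.default_rng(seed)
    clusters = select_clusters(interface, structure, n_clusters=n_clusters,
                               seed=int(rng.integers(2 ** 31)))
    beta = 1.0 / (KB * temperature_K) if temperature_K > 0 else np.inf
    current = model.evaluate(out.coords)[0].total
    n_prop = n_acc = 0
    scratch = out.copy()
    for cluster in clusters:
        movable = [(c, r) for (c, r) in cluster
                   if chem.n_chi(out.residue_name_of(c, r)) > 0]
        if not movable:
            continue
        for _step in range(n_mc_steps):
            scratch.coords[:] = out.coords
            for (c, r) in movable:
                rname = scratch.residue_name_of(c, r)
                rots = library.get(rname)
                probs = np.array([p for _x, p in rots])
                k = int(rng.choice(len(rots), p=probs / probs.sum()))
                set_sidechain_chis(scratch, c, r, rots[k][0])
            n_prop += 1
            if not model.clash_free(scratch.coords, movable, vdw_scale):
                continue
            proposed = model.evaluate(scratch.coords)[0].total
            delta = proposed - current
            if delta <= 0 or (np.isfinite(beta)
                              and rng.random() < np.exp(-beta * delta)):
                out.coords[:] = scratch.coords
                current = proposed
                n_acc += 1
    if stats is not None:
        stats["proposed"] = n_prop
        stats["accepted"] = n_acc
    return out
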