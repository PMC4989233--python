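"""The full refinement pipeline.

One run: detect the interface and anchor restraints to the input model,
minimize, relax for 1.2 ps, then 22 cycles of [interface side-chain MC
repacking at 70 % vdW radii + 0.6 ps relaxation], with the temperature
held at 300 K and annealed linearly down to 50 K over the last six
cycles, and a final minimization.  Each restraint protocol (1: distance
restraints only; 2: distance + CA position restraints) generates 16 such
runs from distinct sub-seeds; the five lowest-energy models per protocol
are returned, ranked 1-5 (protocol 1) and 6-10 (protocol 2).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .energy import EnergyModel, EnergyWeights
from .errors import AllRunsFailed, NonFiniteEnergy
from .params import RotamerLibrary, StatTables, load_rotamer_library
from .restraints import RestraintWeights, build_restraints, detect_interface
from .sampling import MDParams, md_relax, minimize, repack_interface
from .structure import ComplexStructure
from .structure_io import SymmetryGroup, estimate_symmetry


@dataclass
class RefinementConfig:
    """Schedule and ensemble settings (defaults follow the protocol)."""

    n_cycles: int = 22
    init_md_ps: float = 1.2
    cycle_md_ps: float = 0.6
    timestep_fs: float = 4.0
    T_high: float = 300.0
    T_low: float = 50.0
    n_anneal_cycles: int = 6
    n_models_per_protocol: int = 16
    n_select: int = 5
    protocols: tuple = (1, 2)
    symmetric: bool = False
    master_seed: int = 0
    friction: float = 1.0
    repack_vdw_scale: float = 0.7
    n_mc_steps: int = 3
    n_repack_clusters: int = 3
    minimize_steps: int = 150
    minimize_tol: float = 1e-3
    interface_cutoff: float = 8.0
    include_restraints_in_score: bool = True
    energy_weights: EnergyWeights = field(default_factory=EnergyWeights)
    restraint_weights: RestraintWeights = field(
        default_factory=RestraintWeights)

    def validate(self):
        if self.n_anneal_cycles > self.n_cycles:
            raise ValueError("n_anneal_cycles must be <= n_cycles")
        if self.n_select > self.n_models_per_protocol:
            raise ValueError("n_select must be <= n_models_per_protocol")
        if not set(self.protocols) <= {1, 2}:
            raise ValueError("protocols must be a subset of {1, 2}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RefinementConfig":
        with open(str(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RefinementConfig":
        kwargs = dict(raw)
        if "energy_weights" in kwargs:
            kwargs["energy_weights"] = EnergyWeights.from_dict(
                kwargs["energy_weights"])
        if "restraint_weights" in kwargs:
            kwargs["restraint_weights"] = RestraintWeights(
                **kwargs["restraint_weights"])
        if "protocols" in kwargs:
            kwargs["protocols"] = tuple(int(p) for p in kwargs["protocols"])
        return cls(**kwargs).validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["protocols"] = list(self.protocols)
        return d


@dataclass
class RefinedModel:
    structure: ComplexStructure
    final_energy: object                 # EnergyBreakdown
    protocol: int
    run_index: int
    seed: int
    rank: int | None = None
    log: list = field(default_factory=list)

    @property
    def score(self) -> float:
        return self.final_energy.total


def anneal_temperature(cycle_index: int, config: RefinementConfig) -> float:
    """Cycle temperature: T_high on the plateau, then linear to T_low."""
    if not 1 <= cycle_index <= config.n_cycles:
        raise IndexError(f"cycle_index {cycle_index} out of range")
    plateau = config.n_cycles - config.n_anneal_cycles
    if cycle_index <= plateau or config.n_anneal_cycles == 0:
        return config.T_high
    frac = (cycle_index - plateau) / config.n_anneal_cycles
    return config.T_high + (config.T_low - config.T_high) * frac


def refine_once(structure: ComplexStructure, config: RefinementConfig,
                protocol_id: int, run_seed: int,
                library: RotamerLibrary | None = None,
                tables: StatTables | None = None, ff=None) -> RefinedModel:
    """One complete refinement trajectory under one restraint protocol."""
    config.validate()
    library = library or load_rotamer_library()
    rng = np.random.default_rng(run_seed)

    interface = detect_interface(structure, config.interface_cutoff)
    restraints = build_restraints(structure, interface, protocol_id,
                                  config.restraint_weights)
    weights = dataclasses.replace(config.energy_weights)
    if protocol_id == 1:
        weights.restraint_position = 0.0

    symmetry: SymmetryGroup | None = None
    if config.symmetric:
        symmetry = estimate_symmetry(structure)

    model = EnergyModel(structure, restraints, weights, ff=ff,
                        tables=tables)
    model_mc = EnergyModel(structure, restraints, weights, ff=ff,
                           tables=tables,
                           vdw_scale=config.repack_vdw_scale)
    log: list = []
    current = minimize(structure, model=model,
                       max_steps=config.minimize_steps,
                       tol=config.minimize_tol)
    log.append({"phase": "initial_minimize",
                "energy": model.evaluate(current.coords)[0].total})
    init_md = MDParams(timestep_fs=config.timestep_fs,
                       duration_ps=config.init_md_ps,
                       temperature_K=config.T_high,
                       friction=config.friction,
                       seed=int(rng.integers(2 ** 31)))
    current = md_relax(current, params=init_md, symmetry=symmetry,
                       model=model)
    log.append({"phase": "initial_md", "duration_ps": config.init_md_ps,
                "n_steps": init_md.n_steps,
                "temperature_K": config.T_high,
                "energy": model.evaluate(current.coords)[0].total})

    for cycle in range(1, config.n_cycles + 1):
        temp = anneal_temperature(cycle, config)
        stats: dict = {}
        current = repack_interface(
            current, interface, library,
            n_mc_steps=config.n_mc_steps,
            n_clusters=config.n_repack_clusters,
            vdw_scale=config.repack_vdw_scale,
            seed=int(rng.integers(2 ** 31)),
            temperature_K=temp, model=model_mc, stats=stats)
        md = MDParams(timestep_fs=config.timestep_fs,
                      duration_ps=config.cycle_md_ps,
                      temperature_K=temp, friction=config.friction,
                      seed=int(rng.integers(2 ** 31)))
        current = md_relax(current, params=md, symmetry=symmetry,
                           model=model)
        log.append({"phase": "cycle", "cycle": cycle,
                    "temperature_K": temp,
                    "n_clusters": config.n_repack_clusters,
                    "n_mc_steps": config.n_mc_steps,
                    "mc_proposed": stats.get("proposed", 0),
                    "mc_accepted": stats.get("accepted", 0),
                    "md_ps": config.cycle_md_ps, "md_steps": md.n_steps,
                    "energy": model.evaluate(current.coords)[0].total})

    current = minimize(current, model=model,
                       max_steps=config.minimize_steps,
                       tol=config.minimize_tol)
    if config.symmetric and symmetry is not None:
        from .structure_io import enforce_symmetry
        current = enforce_symmetry(current, symmetry)
    score_weights = dataclasses.replace(weights)
    if not config.include_restraints_in_score:
        score_weights.restraint_distance = 0.0
        score_weights.restraint_position = 0.0
    score_model = EnergyModel(structure, restraints, score_weights, ff=ff,
                              tables=tables)
    final = score_model.evaluate(current.coords)[0]
    if not np.isfinite(final.total):
        raise NonFiniteEnergy("non-finite final energy")
    log.append({"phase": "final_minimize", "energy": final.total})
    current.provenance = f"refined-p{protocol_id}-seed{run_seed}"
    return RefinedModel(structure=current, final_energy=final,
                        protocol=protocol_id, run_index=0, seed=run_seed,
                        log=log)


def run_pipeline(structure: ComplexStructure, config: RefinementConfig,
                 library: RotamerLibrary | None = None,
                 tables: StatTables | None = None, ff=None) -> list:
    """Full ensemble: n runs per protocol, select the n_select lowest-
    energy models per protocol, rank 1..5 then 6..10."""
    config.validate()
    ss = np.random.SeedSequence(config.master_seed)
    ranked: list[RefinedModel] = []
    any_success = False
    rank_offset = 0
    for protocol_id in sorted(config.protocols):
        runs: list[RefinedModel] = []
        children = ss.spawn(config.n_models_per_protocol)
        for run_index, child in enumerate(children, start=1):
            seeds = child.generate_state(2)
            run_seed = int(seeds[0] % (2 ** 31))
            try:
                model = refine_once(structure, config, protocol_id,
                                    run_seed, library=library,
                                    tables=tables, ff=ff)
            except NonFiniteEnergy:
                retry = dataclasses.replace(
                    config, timestep_fs=config.timestep_fs / 2.0)
                try:
                    model = refine_once(structure, retry, protocol_id,
                                        int(seeds[1] % (2 ** 31)),
                                        library=library, tables=tables,
                                        ff=ff)
                except NonFiniteEnergy:
                    continue
            model.run_index = run_index
            runs.append(model)
        if not runs:
            continue
        any_success = True
        runs.sort(key=lambda m: (m.score, m.run_index))
        for k, model in enumerate(runs[:config.n_select], start=1):
            model.rank = rank_offset + k
            ranked.append(model)
        rank_offset += config.n_select
    if not any_success:
        raise AllRunsFailed("every refinement run failed")
    return ranked
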