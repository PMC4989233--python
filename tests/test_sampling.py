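import numpy as np
import pytest

from refinecomplex import (EnergyModel, EnergyWeights, MDParams,
                           build_restraints, detect_interface, md_relax,
                           minimize, repack_interface, select_clusters)
from refinecomplex.params import apply_forcefield
from refinecomplex.restraints import (InterfaceSet, PositionRestraint,
                                      RestraintSet)
from refinecomplex.sampling import KB, kinetic_trace
from refinecomplex.structure_io import estimate_symmetry
from refinecomplex.synthetic import set_sidechain_chis

from .conftest import single_atom_structure


def harmonic_system(forcefield, n_atoms=8, weight=1.0, seed=0):
    """Independent 3-D harmonic oscillators: position-restrained atoms."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-20, 20, size=(n_atoms, 3))
    st = single_atom_structure(coords=coords)
    apply_forcefield(st, forcefield)
    rs = RestraintSet(protocol=2)
    for k in range(n_atoms):
        rs.position.append(PositionRestraint(("A", k + 1, "CA"),
                                             coords[k].copy(), weight))
    w = EnergyWeights(**{t: 0.0 for t in
                         ("bonded", "vdw", "coulomb", "solv_polar",
                          "solv_nonpolar", "hbond", "pairstat", "rama",
                          "rotamer")})
    model = EnergyModel(st, rs, w, ff=forcefield)
    return st, rs, w, model


class TestMinimize:
    def test_never_increases_energy(self, dimer, dimer_model):
        rng = np.random.default_rng(0)
        noisy = dimer.with_coords(
            dimer.coords + rng.normal(scale=0.1, size=dimer.coords.shape))
        e0 = dimer_model.evaluate(noisy.coords)[0].total
        out = minimize(noisy, model=dimer_model, max_steps=100)
        e1 = dimer_model.evaluate(out.coords)[0].total
        assert e1 <= e0

    def test_already_minimal_fixed_point(self, forcefield):
        st, _rs, _w, model = harmonic_system(forcefield)
        out = minimize(st, model=model, tol=1e-8)
        assert np.allclose(out.coords, st.coords, atol=1e-6)

    def test_quadratic_bowl_returns_to_origin(self, forcefield):
        st, rs, _w, model = harmonic_system(forcefield, n_atoms=1)
        displaced = st.with_coords(st.coords + np.array([[1.0, 0, 0]]))
        out = minimize(displaced, model=model, tol=1e-8, max_steps=500)
        assert np.allclose(out.coords, rs.position[0].r0, atol=1e-4)

    def test_lj_pair_converges_to_rmin(self, forcefield):
        from .test_energy import neutral_pair
        rmin = 2 * forcefield.vdw("C")[0]
        st = neutral_pair(0.9 * rmin, forcefield)
        w = EnergyWeights(**{t: 0.0 for t in
                             ("bonded", "coulomb", "solv_polar",
                              "solv_nonpolar", "hbond", "pairstat", "rama",
                              "rotamer")})
        model = EnergyModel(st, weights=w, ff=forcefield)
        out = minimize(st, model=model, tol=1e-10, max_steps=500)
        sep = np.linalg.norm(out.coords[1] - out.coords[0])
        assert abs(sep - rmin) < 1e-3

    def test_deterministic(self, dimer, dimer_model):
        rng = np.random.default_rng(1)
        noisy = dimer.with_coords(
            dimer.coords + rng.normal(scale=0.05, size=dimer.coords.shape))
        a = minimize(noisy, model=dimer_model)
        b = minimize(noisy, model=dimer_model)
        assert np.array_equal(a.coords, b.coords)


class TestMDRelax:
    def test_zero_duration_identity(self, dimer, dimer_model):
        out = md_relax(dimer, params=MDParams(duration_ps=0.0),
                       model=dimer_model)
        assert np.array_equal(out.coords, dimer.coords)

    def test_fixed_seed_bit_identical(self, dimer, dimer_model):
        p = MDParams(duration_ps=0.1, temperature_K=300.0, seed=9)
        a = md_relax(dimer, params=p, model=dimer_model)
        b = md_relax(dimer, params=p, model=dimer_model)
        assert np.array_equal(a.coords, b.coords)

    def test_zero_temperature_descends(self, forcefield):
        st, _rs, _w, model = harmonic_system(forcefield, n_atoms=4)
        displaced = st.with_coords(st.coords + 0.8)
        e0 = model.evaluate(displaced.coords)[0].total
        out = md_relax(displaced,
                       params=MDParams(duration_ps=0.4, temperature_K=0.0,
                                       friction=20.0),
                       model=model)
        assert model.evaluate(out.coords)[0].total <= e0

    def test_equipartition_harmonic(self, forcefield):
        st, _rs, _w, model = harmonic_system(forcefield, n_atoms=12)
        params = MDParams(duration_ps=12.0, temperature_K=300.0,
                          friction=2.0, seed=3)
        ke = kinetic_trace(st, params, model=model)
        ndof = st.n_atoms * 3
        per_dof = ke[len(ke) // 4:].mean() / ndof
        assert abs(per_dof - KB * 300 / 2) < 0.1 * KB * 300 / 2

    def test_symmetric_run_exactly_symmetric(self, trimer_c3):
        group = estimate_symmetry(trimer_c3)
        iface = detect_interface(trimer_c3)
        rs = build_restraints(trimer_c3, iface, protocol=1)
        model = EnergyModel(trimer_c3, rs)
        out = md_relax(trimer_c3, params=MDParams(duration_ps=0.1, seed=5),
                       symmetry=group, model=model)
        a = out.coords[out.chain_atoms("A")]
        for k, cid in enumerate(out.chain_ids):
            R, t = group.transform(k)
            assert np.allclose(out.coords[out.chain_atoms(cid)],
                               a @ R.T + t, atol=1e-9)


class TestSelectClusters:
    def test_small_interface_all_members(self, dimer):
        iface = InterfaceSet(frozenset(
            sorted(detect_interface(dimer).members)[:3]))
        clusters = select_clusters(iface, dimer, n_clusters=3, max_size=5,
                                   seed=0)
        assert len(clusters) == 3
        seeds = [c[0] for c in clusters]
        assert len(set(seeds)) == 3
        for c in clusters:
            assert set(c) == set(iface.members)

    def test_single_residue_interface(self, dimer):
        iface = InterfaceSet(frozenset(
            [sorted(detect_interface(dimer).members)[0]]))
        clusters = select_clusters(iface, dimer, n_clusters=3, seed=1)
        assert len(clusters) == 3
        assert all(c == clusters[0] and len(c) == 1 for c in clusters)

    def test_nearest_neighbor_oracle(self, dimer12):
        iface = detect_interface(dimer12)
        clusters = select_clusters(iface, dimer12, n_clusters=3, max_size=4,
                                   seed=2)
        members = iface.sorted_members()
        ca = {m: dimer12.coords[dimer12.atom_index(m[0], m[1], "CA")]
              for m in members}
        for cluster in clusters:
            assert 1 <= len(cluster) <= 4
            seed_res = cluster[0]
            dists = sorted(members,
                           key=lambda m: (np.linalg.norm(ca[m]
                                                         - ca[seed_res])))
            assert set(cluster) == set(dists[:len(cluster)])


class TestRepack:
    def _setup(self, st, protocol=1, vdw_scale=0.7):
        iface = detect_interface(st)
        rs = build_restraints(st, iface, protocol)
        model = EnergyModel(st, rs, vdw_scale=vdw_scale)
        return iface, rs, model

    def test_backbone_and_noninterface_bit_identical(self, dimer12,
                                                     library):
        iface, _rs, model = self._setup(dimer12)
        out = repack_interface(dimer12, iface, library, seed=3, model=model)
        bb = dimer12.is_backbone
        assert np.array_equal(out.coords[bb], dimer12.coords[bb])
        iface_res = set(iface.members)
        for i in range(dimer12.n_atoms):
            cid = dimer12.chain_ids[dimer12.chain_index[i]]
            if (cid, int(dimer12.res_index[i])) not in iface_res:
                assert np.array_equal(out.coords[i], dimer12.coords[i])

    def test_fixed_seed_bit_identical(self, dimer12, library):
        iface, _rs, model = self._setup(dimer12)
        a = repack_interface(dimer12, iface, library, seed=7, model=model)
        b = repack_interface(dimer12, iface, library, seed=7, model=model)
        assert np.array_equal(a.coords, b.coords)

    def test_empty_interface_identity(self, dimer, library):
        iface = InterfaceSet(frozenset())
        out = repack_interface(dimer, iface, library, seed=0)
        assert np.array_equal(out.coords, dimer.coords)

    def test_nonrotatable_interface_identity(self, dimer, library):
        # restrict the interface to residues without rotatable chi
        members = [m for m in detect_interface(dimer).members
                   if dimer.residue_name_of(*m) in ("ALA", "GLY", "PRO")]
        if not members:
            pytest.skip("fixture has no non-rotatable interface residues")
        iface = InterfaceSet(frozenset(members))
        _if, _rs, model = self._setup(dimer)
        out = repack_interface(dimer, iface, library, seed=0, model=model)
        assert np.array_equal(out.coords, dimer.coords)

    def test_low_temperature_single_residue_brute_force(self, dimer12,
                                                        library):
        iface_all = detect_interface(dimer12)
        target = next(m for m in iface_all.sorted_members()
                      if len(library.get(dimer12.residue_name_of(*m))) > 1)
        iface = InterfaceSet(frozenset([target]))
        _if, rs, model = self._setup(dimer12)
        # brute force: try every rotamer, keep non-clashing minimum
        best = None
        rname = dimer12.residue_name_of(*target)
        for chis, _p in library.get(rname):
            trial = dimer12.copy()
            set_sidechain_chis(trial, target[0], target[1], chis)
            if not model.clash_free(trial.coords, [target], 0.7):
                continue
            e = model.evaluate(trial.coords)[0].total
            if best is None or e < best:
                best = e
        e_in = model.evaluate(dimer12.coords)[0].total
        best = min(best, e_in)  # repack may also keep the input
        out = repack_interface(dimer12, iface, library, n_mc_steps=60,
                               n_clusters=1, seed=5, temperature_K=1e-6,
                               model=model)
        e_out = model.evaluate(out.coords)[0].total
        assert e_out <= best + 1e-6

    def test_rebuilt_chis_match_rotamer(self, dimer12, library):
        from refinecomplex import chemistry as chem
        target = next(m for m in detect_interface(dimer12).sorted_members()
                      if chem.n_chi(dimer12.residue_name_of(*m)) > 0)
        rname = dimer12.residue_name_of(*target)
        chis = library.get(rname)[0][0]
        trial = dimer12.copy()
        set_sidechain_chis(trial, target[0], target[1], chis)
        amap = {trial.atom_name[i]: trial.coords[i]
                for i in trial.chain_atoms(target[0])
                if trial.res_index[i] == target[1]}
        got = chem.measure_chis(rname, amap)
        for want, meas in zip(chis, got):
            assert abs((want - meas + 180) % 360 - 180) < 1e-6
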