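"""Integrator, thermostat and neighbor-list correctness."""

import numpy as np
import pytest

from nanobrush import (ForceField, Geometry, IntegratorParams, build_cylinder,
                       build_planar, compute_forces, neighbor_pairs, run)
from nanobrush.engine import final_state
from nanobrush.errors import BondOverstretchError, IntegrationBlowupError
from nanobrush.force_field import MONOMER, NANOPARTICLE, pair_energy
from nanobrush.geometry import PLANAR
from tests.conftest import make_system


def brute_force_pairs(positions, geom, cutoff):
    """All-pairs oracle with explicit minimum-image enumeration."""
    n = len(positions)
    out = set()
    for i in range(n - 1):
        for j in range(i + 1, n):
            dr = positions[i] - positions[j]
            best = np.inf
            for sx in (-1, 0, 1):
                for sy in (-1, 0, 1):
                    for sz in (-1, 0, 1):
                        shift = np.array([sx, sy, sz]) * np.asarray(geom.box)
                        shift[~geom.periodic] = np.where(
                            np.array([sx, sy, sz])[~geom.periodic] == 0,
                            0.0, np.nan)
                        if np.any(np.isnan(shift)):
                            continue
                        d = np.linalg.norm(dr + shift)
                        best = min(best, d)
            if best < cutoff:
                out.add((i, j))
    return out


class TestNeighborList:
    def test_matches_all_pairs_oracle_across_periodic_boundaries(self):
        rng = np.random.default_rng(0)
        geom = Geometry(kind=PLANAR, box=(6.0, 6.0, 8.0), sigma_g=1.0)
        pos = rng.uniform([0, 0, 0.5], [6, 6, 7.5], size=(20, 3))
        # particles hugging the periodic boundary exercise wrapping
        pos[0] = [0.05, 5.95, 3.0]
        pos[1] = [5.95, 0.05, 3.0]
        sys_ = make_system(pos)
        got = {tuple(p) for p in neighbor_pairs(sys_, geom, 2.5)}
        assert got == brute_force_pairs(pos, geom, 2.5)

    def test_cell_build_agrees_with_direct_scan(self):
        rng = np.random.default_rng(1)
        geom = Geometry(kind=PLANAR, box=(20.0, 20.0, 20.0), sigma_g=1.0)
        pos = rng.uniform([0, 0, 0.5], [20, 20, 19.5], size=(600, 3))
        sys_ = make_system(pos)
        # n >= 512 and >= 3 cells per periodic dim: cell path is active
        got = {tuple(p) for p in neighbor_pairs(sys_, geom, 3.4)}
        expect = set()
        for i in range(599):
            dr = geom.minimum_image(pos[i + 1:] - pos[i])
            for k in np.nonzero(np.sum(dr**2, axis=1) < 3.4**2)[0]:
                expect.add((i, int(i + 1 + k)))
        assert got == expect

    def test_pair_energy_from_list_matches_double_loop(self, ff):
        rng = np.random.default_rng(2)
        geom = Geometry(kind=PLANAR, box=(7.0, 7.0, 9.0), sigma_g=1.0)
        pos = rng.uniform([0, 0, 1], [7, 7, 8], size=(20, 3))
        species = np.array([MONOMER] * 12 + [NANOPARTICLE] * 8, dtype=np.int8)
        sys_ = make_system(pos, species=species)
        _, e = compute_forces(sys_, ff, geom, include_wall=False)
        expect = 0.0
        kinds = ["monomer"] * 12 + ["nanoparticle"] * 8
        for i in range(19):
            for j in range(i + 1, 20):
                r = np.linalg.norm(geom.minimum_image(pos[i] - pos[j]))
                expect += pair_energy(r, kinds[i], kinds[j], ff)
        assert e["pair"] == pytest.approx(expect, abs=1e-12)


class TestIntegration:
    def test_free_particle_moves_ballistically(self, ff):
        geom = Geometry(kind=PLANAR, box=(50.0, 50.0, 50.0), sigma_g=1.0)
        v0 = np.array([[0.3, -0.2, 0.1]])
        sys_ = make_system([[10.0, 20.0, 25.0]], species=[NANOPARTICLE],
                           velocities=v0)
        ip = IntegratorParams(gamma=0.0, T=1.0, n_steps_prod=200,
                              snapshot_stride=50, seed=1)
        traj = run(sys_, ff, geom, ip)
        for k, step_idx in enumerate(traj.steps):
            expect = sys_.positions[0] + v0[0] * ip.dt * step_idx
            np.testing.assert_allclose(traj.positions[k, 0], expect,
                                       atol=1e-12)

    def test_identical_seeds_identical_snapshots(self, ff):
        sys_, geom = build_planar(4, 10, n_np=30, seed=7)
        ip = IntegratorParams(T=1.2, seed=42, n_steps_equil=500,
                              n_steps_prod=500, snapshot_stride=100)
        t1 = run(sys_, ff, geom, ip)
        t2 = run(sys_, ff, geom, ip)
        np.testing.assert_array_equal(t1.positions, t2.positions)
        t3 = run(sys_, ff, geom,
                 IntegratorParams(T=1.2, seed=43, n_steps_equil=500,
                                  n_steps_prod=500, snapshot_stride=100))
        assert not np.array_equal(t1.positions, t3.positions)

    def test_empty_production_gives_empty_trajectory(self, ff):
        sys_, geom = build_planar(2, 5, seed=0)
        ip = IntegratorParams(n_steps_equil=100, n_steps_prod=0, seed=0)
        traj = run(sys_, ff, geom, ip)
        assert traj.n_frames == 0

    def test_nve_energy_is_conserved_short(self, ff):
        """Thermostat off: no secular energy drift (quick check)."""
        sys_, geom = build_planar(16, 40, seed=1)
        relaxed = final_state(sys_, ff, geom,
                              IntegratorParams(T=1.0, seed=4,
                                               n_steps_equil=3000))
        ip = IntegratorParams(gamma=0.0, T=1.0, seed=5, n_steps_equil=0,
                              n_steps_prod=2000, snapshot_stride=0,
                              log_stride=5)
        traj = run(relaxed, ff, geom, ip)
        n_free = int((~sys_.frozen).sum())
        th = traj.thermo
        etot = (1.5 * n_free * th.T_inst + th.E_pair + th.E_bond
                + th.E_wall).to_numpy()
        q = len(etot) // 4
        drift = abs(etot[-q:].mean() - etot[:q].mean()) / sys_.n_particles
        assert drift < 3e-4

    def test_thermostat_reaches_target_temperature(self, ff):
        sys_, geom = build_planar(0, 1, n_np=200, T=0.5, seed=8)
        ip = IntegratorParams(gamma=1.0, T=1.5, seed=9, n_steps_equil=0,
                              n_steps_prod=20_000, snapshot_stride=0,
                              log_stride=200)
        traj = run(sys_, ff, geom, ip)
        tail = traj.thermo.T_inst.iloc[50:]
        assert tail.mean() == pytest.approx(1.5, rel=0.05)

    def test_bonds_stay_below_maximum_extension(self, ff):
        sys_, geom = build_planar(4, 20, seed=6)
        ip = IntegratorParams(T=2.0, seed=10, n_steps_equil=0,
                              n_steps_prod=5000, snapshot_stride=500)
        traj = run(sys_, ff, geom, ip)
        for fr in range(traj.n_frames):
            dr = geom.minimum_image(
                traj.positions[fr, traj.chains[:, :-1].ravel()]
                - traj.positions[fr, traj.chains[:, 1:].ravel()])
            assert np.linalg.norm(dr, axis=1).max() < ff.fene_r0

    def test_graft_anchors_never_move(self, ff):
        sys_, geom = build_planar(4, 10, seed=2)
        ip = IntegratorParams(T=3.0, seed=3, n_steps_equil=1000,
                              n_steps_prod=1000, snapshot_stride=200)
        traj = run(sys_, ff, geom, ip)
        heads = traj.chains[:, 0]
        for fr in range(traj.n_frames):
            np.testing.assert_array_equal(traj.positions[fr, heads],
                                          sys_.graft_anchors)

    def test_blowup_reports_step_index(self, ff):
        sys_, geom = build_planar(2, 5, seed=1)
        sys_.velocities[1] = [0.0, 0.0, 400.0]  # guarantees overstretch
        ip = IntegratorParams(gamma=0.0, T=1.0, seed=0, n_steps_equil=0,
                              n_steps_prod=100, snapshot_stride=0)
        with pytest.raises((BondOverstretchError, IntegrationBlowupError)):
            run(sys_, ff, geom, ip)

    def test_pair_and_bond_forces_cancel_internally(self, ff):
        """Newton's third law: without walls, internal forces sum to zero."""
        sys_, geom = build_planar(6, 8, n_np=40, seed=12)
        f, _ = compute_forces(sys_, ff, geom, include_wall=False)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-10)


class TestCylinderDynamics:
    def test_wall_permeable_to_nanoparticles_but_not_monomers(self):
        ff = ForceField(eps_b=1.5)
        sys_, geom = build_cylinder(24, 16, R=8.0, box_pad=6.0, n_np=60,
                                    T=1.0, seed=4)
        ip = IntegratorParams(T=1.0, seed=6, n_steps_equil=5000,
                              n_steps_prod=5000, snapshot_stride=1000)
        traj = run(sys_, ff, geom, ip)
        mobile_mono = (traj.species == MONOMER)
        mobile_mono[traj.chains[:, 0]] = False  # anchors sit on the surface
        nano = traj.species == NANOPARTICLE
        inside = outside = 0
        for fr in range(traj.n_frames):
            rho_m = geom.radial_distance(traj.positions[fr, mobile_mono])
            assert rho_m.max() < geom.R
            rho_n = geom.radial_distance(traj.positions[fr, nano])
            inside += int((rho_n < geom.R).sum())
            outside += int((rho_n > geom.R).sum())
        assert inside > 0 and outside > 0
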