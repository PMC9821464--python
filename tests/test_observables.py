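"""Density-profile normalizations, brush height, concentration, diagrams."""

import numpy as np
import pytest

from nanobrush import (BrushStatePoint, Geometry, brush_height, hc_diagram,
                       profile_flat, profile_projection, profile_radial,
                       scaling_collapse, solution_concentration, state_point)
from nanobrush.errors import AnalysisError
from nanobrush.force_field import MONOMER, NANOPARTICLE
from nanobrush.geometry import CYLINDER, PLANAR
from nanobrush.observables import DensityProfile
from tests.conftest import make_traj


def planar_brush_traj(n_chains=16, N=40, sigma_g=0.0625, Lz=60.0,
                      n_np=0, n_frames=3, seed=0):
    """Random monomer cloud with proper chain bookkeeping (no dynamics)."""
    rng = np.random.default_rng(seed)
    L = np.sqrt(n_chains / sigma_g)
    geom = Geometry(kind=PLANAR, box=(L, L, Lz), sigma_g=sigma_g)
    n_mono = n_chains * N
    frames = rng.uniform([0, 0, 0.2], [L, L, 0.6 * Lz],
                         size=(n_frames, n_mono + n_np, 3))
    frames[:, n_mono:, 2] = rng.uniform(0.2, Lz - 0.2,
                                        size=(n_frames, n_np))
    species = np.array([MONOMER] * n_mono + [NANOPARTICLE] * n_np,
                       dtype=np.int8)
    chains = np.arange(n_mono, dtype=np.int32).reshape(n_chains, N)
    return make_traj(frames, geom, species=species, chains=chains)


class TestFlatProfile:
    def test_monomer_integral_is_sigma_g_times_N(self):
        traj = planar_brush_traj(n_chains=100, N=100, Lz=150.0)
        prof = profile_flat(traj)
        assert prof.integral() == pytest.approx(6.25, abs=1e-10)

    def test_single_delta_snapshot_mass_in_one_bin(self):
        traj = planar_brush_traj(n_chains=4, N=10, n_frames=1)
        traj.positions[0, :, 2] = 5.0
        prof = profile_flat(traj, bin_width=1.0)
        nz = np.nonzero(prof.values)[0]
        assert len(nz) == 1
        assert prof.bin_edges[nz[0]] <= 5.0 < prof.bin_edges[nz[0] + 1]
        assert prof.integral() == pytest.approx(0.0625 * 10, abs=1e-10)

    def test_nanoparticle_profile_normalized_to_unity(self):
        traj = planar_brush_traj(n_np=50, seed=3)
        prof = profile_flat(traj, species="nanoparticle")
        assert prof.mode == "np_phibar"
        assert prof.integral() == pytest.approx(1.0, abs=1e-10)

    def test_empty_trajectory_rejected(self, planar_geom):
        traj = make_traj(np.zeros((0, 4, 3)), planar_geom)
        with pytest.raises(AnalysisError):
            profile_flat(traj)


def cylinder_traj(points, R=10.0, L=8.0, n_chains=4, N=None, seed=0,
                  species=None, anchors=None, chains=None):
    side = 2 * R + 10.0
    geom = Geometry(kind=CYLINDER, box=(L, side, side), sigma_g=0.0625, R=R)
    if chains is None:
        n = points.shape[-2]
        N = n // n_chains
        chains = np.arange(n_chains * N, dtype=np.int32).reshape(n_chains, N)
    return make_traj(points, geom, species=species, chains=chains,
                     anchors=anchors), geom


class TestRadialProfile:
    def test_normalization_identity(self):
        rng = np.random.default_rng(1)
        R, L, n = 10.0, 8.0, 4000
        u = rng.uniform(0, 1, n)
        rho = R * np.sqrt(u)
        th = rng.uniform(0, 2 * np.pi, n)
        pts = np.stack([rng.uniform(0, L, n), R + 5 + rho * np.cos(th),
                        R + 5 + rho * np.sin(th)], axis=1)
        traj, geom = cylinder_traj(pts[None], n_chains=8)
        prof = profile_radial(traj)
        # 2 pi L * sum (R - r_mid) psi dr == N * n_chains
        mids = prof.bin_centers
        lhs = 2 * np.pi * L * np.sum((R - mids) * prof.values
                                     * prof.bin_width)
        assert lhs == pytest.approx(4000, rel=1e-8)

    def test_wall_hugging_monomers_fill_first_bin(self):
        R, L = 10.0, 8.0
        th = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = np.stack([np.full(40, 1.0), R + 5 + (R - 0.01) * np.cos(th),
                        R + 5 + (R - 0.01) * np.sin(th)], axis=1)
        traj, geom = cylinder_traj(pts[None], n_chains=4)
        prof = profile_radial(traj)
        assert np.sum(prof.values > 0) == 1
        assert prof.values[0] > 0

    def test_uniform_cloud_gives_flat_profile(self):
        """Jacobian check: uniform density in the cylinder -> constant psi."""
        rng = np.random.default_rng(2)
        R, L, n = 10.0, 8.0, 200_000
        rho = R * np.sqrt(rng.uniform(0, 1, n))
        th = rng.uniform(0, 2 * np.pi, n)
        pts = np.stack([rng.uniform(0, L, n), R + 5 + rho * np.cos(th),
                        R + 5 + rho * np.sin(th)], axis=1)
        traj, geom = cylinder_traj(pts[None], n_chains=8, R=R, L=L)
        prof = profile_radial(traj, bin_width=0.5)
        # exclude bins near the axis where counts (and the Jacobian) vanish
        keep = prof.bin_centers < 8.0
        vals = prof.values[keep]
        counts = n * (2 * (R - prof.bin_centers[keep]) * 0.5 / R**2)
        rel_sd = 1.0 / np.sqrt(counts)  # Poisson
        dev = np.abs(vals / vals.mean() - 1.0)
        assert np.all(dev < 5 * rel_sd + 0.02)


class TestProjectionProfile:
    def _stretched(self, R=10.0, L=8.0, n_chains=4, N=30, bond=0.97):
        # chains stretched along the inward normal, extending past the axis
        side = 2 * R + 10.0
        cy = cz = side / 2
        geom = Geometry(kind=CYLINDER, box=(L, side, side), sigma_g=0.0625,
                        R=R)
        th = np.linspace(0, 2 * np.pi, n_chains, endpoint=False)
        pts = np.zeros((n_chains * N, 3))
        anchors = np.zeros((n_chains, 3))
        for c, t in enumerate(th):
            a = np.array([1.0 + c, cy + R * np.cos(t), cz + R * np.sin(t)])
            anchors[c] = a
            inward = np.array([0.0, -np.cos(t), -np.sin(t)])
            for j in range(N):
                pts[c * N + j] = a + bond * j * inward
        chains = np.arange(n_chains * N, dtype=np.int32).reshape(n_chains, N)
        traj = make_traj(pts[None], geom, chains=chains, anchors=anchors)
        return traj, (N - 1) * bond

    def test_support_extends_past_the_cylinder_radius(self):
        traj, extent = self._stretched(N=30)
        assert extent > traj.geometry.R
        prof = profile_projection(traj)
        s_max = prof.bin_edges[np.nonzero(prof.values)[0][-1] + 1]
        assert s_max >= extent
        assert s_max <= extent + 2 * prof.bin_width

    def test_normalization_matches_flat_contract(self):
        traj, _ = self._stretched(N=30)
        prof = profile_projection(traj)
        assert prof.integral() == pytest.approx(0.0625 * 30, abs=1e-10)


class TestBrushHeight:
    def test_uniform_profile_quantile(self):
        edges = np.linspace(0, 40, 161)
        prof = DensityProfile(edges, np.full(160, 1.0), "flat_psi", 1.0)
        assert brush_height(prof) == pytest.approx(0.995 * 40, abs=1e-12)

    def test_two_spike_profile_lands_in_upper_bin(self):
        edges = np.linspace(0, 40, 41)
        vals = np.zeros(40)
        vals[10] = vals[30] = 1.0
        prof = DensityProfile(edges, vals, "flat_psi", 1.0)
        h = brush_height(prof)
        assert 30.0 <= h < 31.0

    def test_monotone_under_mass_added_above(self):
        edges = np.linspace(0, 40, 41)
        vals = np.zeros(40)
        vals[:20] = 1.0
        prof = DensityProfile(edges, vals, "flat_psi", 1.0)
        h0 = brush_height(prof)
        vals2 = vals.copy()
        vals2[35] = 0.5
        h1 = brush_height(DensityProfile(edges, vals2, "flat_psi", 1.0))
        assert h1 > h0

    def test_invariant_under_rescaling(self):
        rng = np.random.default_rng(0)
        edges = np.linspace(0, 30, 121)
        vals = rng.uniform(0, 1, 120)
        p1 = DensityProfile(edges, vals, "flat_psi", 1.0)
        p2 = DensityProfile(edges, 7.3 * vals, "flat_psi", 1.0)
        assert brush_height(p1) == pytest.approx(brush_height(p2), abs=1e-12)

    def test_all_zero_profile_rejected(self):
        prof = DensityProfile(np.linspace(0, 1, 5), np.zeros(4),
                              "flat_psi", 1.0)
        with pytest.raises(AnalysisError):
            brush_height(prof)


class TestSolutionConcentration:
    def test_all_nanoparticles_inside_gives_zero(self):
        rng = np.random.default_rng(0)
        R, L = 10.0, 8.0
        rho = rng.uniform(0, R - 1, 30)
        th = rng.uniform(0, 2 * np.pi, 30)
        pts = np.stack([rng.uniform(0, L, 30), R + 5 + rho * np.cos(th),
                        R + 5 + rho * np.sin(th)], axis=1)
        traj, _ = cylinder_traj(pts[None], n_chains=2,
                                species=np.full(30, NANOPARTICLE, np.int8),
                                chains=np.zeros((0, 1), np.int32))
        assert solution_concentration(traj) == 0.0

    def test_uniform_gas_with_zero_brush_height(self, planar_geom):
        rng = np.random.default_rng(1)
        n = 200
        pts = rng.uniform([0, 0, 0], [16, 16, 60], size=(n, 3))
        traj = make_traj(pts[None], planar_geom,
                         species=np.full(n, NANOPARTICLE, np.int8))
        c = solution_concentration(traj, h=0.0)
        assert c == pytest.approx(n / (16 * 16 * 60), rel=1e-12)

    def test_half_outside_cylinder_counts_exactly(self):
        R, L, side = 10.0, 8.0, 30.0
        n_out, n_in = 12, 12
        pts = np.zeros((n_out + n_in, 3))
        pts[:n_out] = [4.0, 2.0, 2.0]       # corner: outside the cylinder
        pts[n_out:] = [4.0, 15.0, 15.0]     # on the axis: inside
        traj, geom = cylinder_traj(
            pts[None], species=np.full(n_out + n_in, NANOPARTICLE, np.int8),
            chains=np.zeros((0, 1), np.int32))
        expect = n_out / (L * side * side - np.pi * R**2 * L)
        assert solution_concentration(traj) == pytest.approx(expect,
                                                             rel=1e-12)

    def test_brush_height_at_box_top_rejected(self, planar_geom):
        traj = make_traj(np.zeros((1, 3, 3)), planar_geom,
                         species=np.full(3, NANOPARTICLE, np.int8))
        with pytest.raises(AnalysisError):
            solution_concentration(traj, h=60.0)


class TestDiagrams:
    def test_single_point_curve(self):
        pt = BrushStatePoint(T=1.0, eps_b=1.0, sigma_n=1.0, h=15.0, c=0.01)
        df = hc_diagram([pt])
        assert len(df) == 1
        assert df.h.iloc[0] == 15.0

    def test_duplicated_replicates_zero_spread(self):
        traj = planar_brush_traj(seed=5)
        sp = state_point([traj, traj], T=1.0, eps_b=1.0, sigma_n=1.0)
        assert sp.h_sd == 0.0
        assert sp.n_replicates == 2

    def test_curves_sorted_by_concentration(self):
        pts = [BrushStatePoint(T=1.0, eps_b=1.0, sigma_n=1.0, h=h, c=c)
               for h, c in [(10, 0.03), (12, 0.01), (11, 0.02)]]
        df = hc_diagram(pts)
        assert list(df.c) == sorted(df.c)

    def test_collapse_identical_curves_scores_zero(self):
        c = np.linspace(0.01, 0.05, 5)
        h = np.array([20, 18, 15, 14, 13.5])
        score = scaling_collapse([(c, h), (c, h)])
        assert score["max"] == 0.0
        assert score["mean"] == 0.0

    def test_collapse_constant_offset_is_the_mean_discrepancy(self):
        c = np.linspace(0.01, 0.05, 5)
        h = np.array([20, 18, 15, 14, 13.5])
        score = scaling_collapse([(c, h), (c, h + 1.0)])
        assert score["mean"] == pytest.approx(1.0, abs=1e-12)
        assert score["max"] == pytest.approx(1.0, abs=1e-12)

    def test_non_overlapping_ranges_rejected(self):
        with pytest.raises(AnalysisError):
            scaling_collapse([(np.array([0.01, 0.02]), np.array([1, 2])),
                              (np.array([0.05, 0.06]), np.array([1, 2]))])
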