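"""Lattice-Boltzmann solver: voxelization and canonical flow oracles."""

import numpy as np
import pytest

from archstent.anatomy import AnatomyConfig, build_dissected_aorta
from archstent.lbm import (FLAG_FLUID, FLAG_INLET, FLAG_OUTLET0, FLAG_SOLID,
                           FluidProps, LatticeConfig, VoxelLattice,
                           run_pulsatile_lbm, voxelize)
from archstent.waveforms import WaveformSpec


def _tube_lattice(R=8, L=60, dx=1e-3):
    nx = ny = 2 * R + 4
    flags = np.zeros((nx, ny, L), np.uint8)
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    inside = (X - (nx - 1) / 2) ** 2 + (Y - (ny - 1) / 2) ** 2 < R * R
    flags[:, :, :] = np.where(inside[:, :, None], FLAG_FLUID, FLAG_SOLID)
    flags[:, :, 0][inside] = FLAG_INLET
    flags[:, :, -1][inside] = FLAG_OUTLET0
    return VoxelLattice(dx=dx, origin=np.zeros(3), flags=flags,
                        region=(flags != 0).astype(np.uint8),
                        branch=np.full(flags.shape, -1, np.int16),
                        inlet_normal=np.array([0.0, 0.0, 1.0]))


class TestVoxelize:
    def test_cylinder_cell_count_matches_volume(self):
        cfg = AnatomyConfig(arch_radius=float("inf"), ascending_length=30,
                            descending_length=30, wall_inner_diameter=20.0,
                            flap_angular_extent_deg=0, tl_min_diameter=10.0,
                            branch_positions=(), branch_diameters=())
        model = build_dissected_aorta(cfg)
        dx = 1.0e-3
        lat = voxelize(model, dx)
        expect = np.pi * 10 ** 2 * 60 / (dx * 1000) ** 3
        assert lat.fluid_count == pytest.approx(expect, rel=0.05)

    def test_halving_dx_scales_cell_count_by_8(self):
        cfg = AnatomyConfig(arch_radius=float("inf"), ascending_length=20,
                            descending_length=20, wall_inner_diameter=16.0,
                            flap_angular_extent_deg=0, tl_min_diameter=10.0,
                            branch_positions=(), branch_diameters=())
        model = build_dissected_aorta(cfg)
        n1 = voxelize(model, 2.0e-3).fluid_count
        n2 = voxelize(model, 1.0e-3).fluid_count
        assert n2 / n1 == pytest.approx(8.0, rel=0.10)

    def test_solid_box_has_no_fluid(self):
        import trimesh
        box = trimesh.creation.box(extents=(5, 5, 5))
        lat = voxelize(box, 10e-3)        # cells larger than the box
        assert lat.fluid_count == 0

    def test_non_watertight_mesh_rejected(self):
        import trimesh
        tri = trimesh.Trimesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        with pytest.raises(ValueError):
            voxelize(tri, 1e-3)

    def test_default_model_flags_regions_and_outlets(self, aorta):
        lat = voxelize(aorta, 2.5e-3)
        assert lat.n_outlets == 1 + len(aorta.branches)
        assert (lat.region == 1).sum() > 0 and (lat.region == 2).sum() > 0
        assert (lat.flags == FLAG_INLET).sum() > 0


class TestStability:
    def test_unstable_tau_rejected(self):
        with pytest.raises(ValueError):
            LatticeConfig(tau=0.4)
        with pytest.raises(ValueError):
            LatticeConfig(tau=2.5)

    def test_mach_violation_rejected(self):
        with pytest.raises(ValueError):
            LatticeConfig(u_lat_peak=0.5)


class TestFlowOracles:
    def test_no_flow_without_driving(self):
        lat = _tube_lattice(R=5, L=20)
        inlet = WaveformSpec("velocity", 0.0)
        outlet = WaveformSpec("pressure", 0.0)
        cfg = LatticeConfig(tau=0.8, u_lat_peak=0.05, samples_per_cycle=2)
        ff = run_pulsatile_lbm(lat, inlet, outlet, config=cfg, n_cycles=1)
        assert np.abs(ff.velocity[-1]).max() < 1e-8

    @pytest.fixture(scope="class")
    def poiseuille(self):
        # Re ~ 3: the entrance length (~0.06 Re D) is a few cells, so the
        # measurement window sits in fully developed flow
        lat = _tube_lattice(R=8, L=60)
        inlet = WaveformSpec("velocity", 0.05)      # steady
        outlet = WaveformSpec("pressure", 0.0)
        cfg = LatticeConfig(tau=0.8, u_lat_peak=0.01, samples_per_cycle=2)
        ff = run_pulsatile_lbm(lat, inlet, outlet, config=cfg, n_cycles=3)
        return ff

    def test_parabolic_profile_ratio(self, poiseuille):
        """Centerline-to-mean velocity ratio of developed laminar pipe flow
        is 2 (Hagen-Poiseuille)."""
        ff = poiseuille
        coords = ff.fluid_index
        mid = coords[:, 2] == 40
        uz = ff.velocity[-1][mid][:, 2]
        assert uz.max() / uz.mean() == pytest.approx(2.0, rel=0.05)

    def test_pressure_drop_matches_hagen_poiseuille(self, poiseuille):
        """dp = 8 mu Q L / (pi a^4) with the hydraulic radius a fitted from
        the computed parabolic profile (the staircase wall makes the nominal
        radius ambiguous by half a cell)."""
        ff = poiseuille
        coords = ff.fluid_index
        lat = ff.lattice
        nx = lat.flags.shape[0]
        mid = coords[:, 2] == 30
        uz = ff.velocity[-1][mid][:, 2].astype(float)
        xy = coords[mid][:, :2] - (nx - 1) / 2
        r2 = (xy ** 2).sum(axis=1) * (lat.dx * 1) ** 2
        A = np.stack([np.ones_like(r2), r2], axis=1)
        c = np.linalg.lstsq(A, uz, rcond=None)[0]
        a2 = -c[0] / c[1]                       # u = c0 (1 - r^2/a^2)
        umax = c[0]
        Q = 0.5 * umax * np.pi * a2             # parabolic profile flux
        mu = ff.info["nu_eff"] * 1060.0
        span = 30 * lat.dx
        p1 = ff.pressure[-1][coords[:, 2] == 15].mean()
        p2 = ff.pressure[-1][coords[:, 2] == 45].mean()
        dp_expect = 8 * mu * Q * span / (np.pi * a2 ** 2)
        assert (p1 - p2) == pytest.approx(dp_expect, rel=0.10)

    def test_steady_mass_balance(self, poiseuille):
        """Volumetric flux is conserved along the developed tube within 1%
        (interior cross-sections, compressibility-corrected by density)."""
        ff = poiseuille
        coords = ff.fluid_index
        rhoish = 1.0 + (ff.pressure[-1] - ff.info["p_ref"]) \
            / ((ff.lattice.dx / ff.info["dt"]) ** 2 / 3 * 1060.0)
        flux = []
        for z in (10, 25, 45):
            m = coords[:, 2] == z
            flux.append(float((ff.velocity[-1][m][:, 2] * rhoish[m]).sum()))
        assert flux[0] == pytest.approx(flux[1], rel=0.01)
        assert flux[1] == pytest.approx(flux[2], rel=0.01)

    def test_divergence_reported_as_error(self):
        lat = _tube_lattice(R=4, L=12)
        inlet = WaveformSpec("velocity", 0.05)
        outlet = WaveformSpec("pressure", 0.0)
        cfg = LatticeConfig(tau=0.505, u_lat_peak=0.16, samples_per_cycle=2)
        with pytest.raises((FloatingPointError, ValueError)):
            run_pulsatile_lbm(lat, inlet, outlet, config=cfg, n_cycles=3)
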