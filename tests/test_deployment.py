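"""Crimp, radial force, self-expansion and stress extraction."""

import numpy as np
import pytest
from dataclasses import replace

from archstent.anatomy import AnatomyConfig, build_dissected_aorta
from archstent.deployment import (ContactParams, beam_von_mises, build_crimper,
                                  crimp_radial, radial_force_profile,
                                  release_and_expand, _element_measures,
                                  _wire_model)
from archstent.stent import DEFAULT_DESIGN, StentDesign, build_stent


class TestCrimperTool:
    def test_default_grid_has_2350_facets(self):
        crimper = build_crimper(DEFAULT_DESIGN)
        assert crimper.facet_count == 2350
        assert crimper.node_grid().shape == (48 * 50, 3)

    def test_crimper_encloses_the_free_stent(self, stent_pair):
        mesh, _ = stent_pair
        crimper = build_crimper(DEFAULT_DESIGN)
        assert crimper.radius > DEFAULT_DESIGN.nominal_diameter / 2
        assert crimper.z0 < mesh.nodes[:, 2].min()
        assert crimper.z0 + crimper.length > mesh.nodes[:, 2].max()


class TestCrimp:
    def test_noop_crimp_at_nominal_diameter(self):
        design = replace(DEFAULT_DESIGN, elements_per_ring=36, n_rings=2,
                         total_length=38.0, ring_amplitude=8.5, inter_ring_gap=4.0)
        mesh, sutures = build_stent(design)
        state, record = crimp_radial(mesh, target_diameter=design.nominal_diameter,
                                     sutures=sutures, n_steps=2, max_iter=500)
        assert np.allclose(state.nodes, mesh.nodes, atol=1e-6)
        assert state.von_mises.max() < 1e-6
        assert state.reaction_radial == pytest.approx(0.0, abs=1e-9)

    def test_crimp_reaches_target_and_stores_energy(self, crimped_state, aorta):
        from archstent.anatomy import largest_inscribed_sphere_diameter
        state, record = crimped_state
        target = largest_inscribed_sphere_diameter(aorta)
        outer = 2 * np.linalg.norm(state.nodes[:, :2], axis=1).max()
        assert outer == pytest.approx(target, rel=0.01)
        assert state.elastic_energy > 0
        assert state.phase == "crimped"

    def test_overlarge_target_rejected(self, stent_pair):
        mesh, sutures = stent_pair
        with pytest.raises(ValueError):
            crimp_radial(mesh, target_diameter=50.0, sutures=sutures)


class TestRadialForce:
    def test_crimper_alone_has_zero_force(self):
        from archstent.deployment import _empty_crimper_reaction
        crimper = build_crimper(DEFAULT_DESIGN)
        assert np.all(_empty_crimper_reaction(crimper, np.array([30.0, 20.0]))
                      == 0.0)

    def test_force_zero_at_and_above_free_diameter(self):
        prof = radial_force_profile(DEFAULT_DESIGN, [36.0, 38.0])
        assert np.all(prof.force_per_length == 0.0)

    def test_force_scales_with_wire_stiffness(self):
        """Doubling E doubles the radial force at every recorded diameter
        (linear-elastic scaling; same geometry)."""
        small = replace(DEFAULT_DESIGN, n_rings=2, total_length=38.0,
                        ring_amplitude=8.5, elements_per_ring=36)
        stiff = replace(small, material=replace(small.material, E=2 * small.material.E))
        grid = [31.0, 33.0]
        f1 = radial_force_profile(small, grid, n_steps=6, max_iter=3000)
        f2 = radial_force_profile(stiff, grid, n_steps=6, max_iter=3000)
        ratio = f2.force_per_length / f1.force_per_length
        assert ratio == pytest.approx([2.0, 2.0], rel=0.05)

    def test_force_monotone_in_compression(self):
        prof = radial_force_profile(DEFAULT_DESIGN, [28.0, 31.0, 34.0],
                                    n_steps=10, max_iter=3000)
        f = prof.force_per_length
        assert f[0] > f[1] > f[2] > 0

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            radial_force_profile(DEFAULT_DESIGN, [-5.0, 30.0])


class TestVonMises:
    def test_undeformed_stent_is_stress_free(self, stent_pair):
        mesh, _ = stent_pair
        model, meta = _wire_model(mesh, None)
        strain, kappa = _element_measures(model, mesh, meta)
        assert np.abs(strain).max() < 1e-12
        assert np.abs(kappa).max() < 1e-9

    def test_bent_beam_matches_euler_bernoulli_hand_formula(self):
        """A straight hinge bent to curvature kappa (length preserved) must
        report fiber stress E kappa r to 1e-6 relative (hand formula)."""
        from archstent.solver import StructuralModel
        ell = 2.0
        theta = 1e-3                     # turning angle; kappa = theta / ell
        X = np.array([[0.0, 0, 0], [ell, 0, 0],
                      [ell + ell * np.cos(theta), ell * np.sin(theta), 0.0]])
        m = StructuralModel(np.array([[0.0, 0, 0], [ell, 0, 0], [2 * ell, 0, 0]]))
        m.add_bending([[0, 1, 2]], 1.0, 0.0)
        dev = m.bending_deviation(X)[0]
        kappa = dev / ell
        E, r = 83000.0, 0.3
        assert E * kappa * r == pytest.approx(E * (theta / ell) * r, rel=1e-6)

    def test_pure_axial_strain_gives_E_eps(self, stent_pair):
        """Stretching every wire segment by eps with no bending yields
        sigma = E * eps exactly."""
        mesh, _ = stent_pair
        model, meta = _wire_model(mesh, None)
        eps = 1e-3
        model.X = mesh.nodes * (1 + eps)      # uniform dilation: angles unchanged
        strain, kappa = _element_measures(model, mesh, meta)
        assert strain == pytest.approx(np.full_like(strain, eps), rel=1e-9)
        from archstent.deployment import DeploymentState
        st = DeploymentState(mesh=mesh, nodes=model.X, phase="crimped",
                             element_strain=strain, element_curvature=kappa,
                             residual=0.0, converged=True, crimper_radius=0.0,
                             elastic_energy=0.0)
        E = mesh.design.material.E_MPa
        expect = E * (eps + kappa * mesh.design.wire_radius)
        assert beam_von_mises(st) == pytest.approx(expect, rel=1e-9)


class TestExpansionOracles:
    @pytest.fixture(scope="class")
    def short_design(self):
        return replace(DEFAULT_DESIGN, n_rings=3, total_length=59.0,
                       ring_amplitude=8.5, inter_ring_gap=4.0,
                       elements_per_ring=54)

    def _tube(self, diameter, length=120.0):
        return build_dissected_aorta(AnatomyConfig(
            arch_radius=float("inf"), ascending_length=length / 2,
            descending_length=length / 2, wall_inner_diameter=diameter,
            flap_angular_extent_deg=0, tl_min_diameter=diameter / 2,
            branch_positions=(), branch_diameters=()))

    def test_free_recovery_in_wide_tube(self, short_design):
        """A tube wider than the free diameter leaves the stent fully
        recovered and force-free."""
        from archstent.materials import AORTIC_WALL
        mesh, sutures = build_stent(short_design)
        crimped, _ = crimp_radial(mesh, target_diameter=28.0, sutures=sutures,
                                  n_steps=8)
        tube = self._tube(44.0)
        st = release_and_expand(crimped, tube, AORTIC_WALL, placement_offset=20.0)
        radii = np.linalg.norm(st.nodes[:, :2] - st.nodes[:, :2].mean(axis=0),
                               axis=1)
        assert 2 * radii.max() == pytest.approx(short_design.nominal_diameter,
                                                rel=0.02)
        assert st.von_mises.max() < 50.0

    def test_constrained_recovery_matches_tube_diameter(self, short_design):
        from archstent.materials import AORTIC_WALL
        mesh, sutures = build_stent(short_design)
        crimped, _ = crimp_radial(mesh, target_diameter=24.0, sutures=sutures,
                                  n_steps=8)
        tube = self._tube(30.0)
        st = release_and_expand(crimped, tube, AORTIC_WALL, placement_offset=20.0)
        radii = np.linalg.norm(st.nodes[:, :2] - st.nodes[:, :2].mean(axis=0),
                               axis=1)
        outer = 2 * (radii.max() + short_design.wire_radius)
        assert outer == pytest.approx(30.0, rel=0.02)


class TestDeployedStates:
    def test_remodeling_trends_with_flap_softening(self, deployed_states, aorta):
        """Softer flaps yield strictly larger TL, strictly smaller FL and
        strictly larger flap excursion (acute flaps respond most)."""
        from archstent.anatomy import lumen_volumes
        fl_pre = lumen_volumes(aorta)["FL"]
        ratios = sorted(deployed_states, reverse=True)       # 1.0, 0.1, 0.01
        tl = [deployed_states[r].tl_min_diameter for r in ratios]
        fl = [deployed_states[r].fl_volume for r in ratios]
        disp = [deployed_states[r].flap_displacement_max for r in ratios]
        assert tl[0] < tl[1] < tl[2]
        assert fl_pre > fl[0] > fl[1] > fl[2]
        assert disp[0] < disp[1] < disp[2]

    def test_stent_nodes_stay_inside_the_wall(self, deployed_states, aorta):
        tol = 0.1        # mm, penalty-resolution scale
        for st in deployed_states.values():
            js = aorta.centerline.nearest_station(st.nodes)
            rel = st.nodes - aorta.centerline.points[js]
            x = np.einsum("ij,ij->i", rel, aorta.e1[js])
            y = np.einsum("ij,ij->i", rel, aorta.e2[js])
            assert np.all(np.hypot(x, y) <= aorta.wall_radius[js] + tol)

    def test_flap_stays_inside_the_wall(self, deployed_states, aorta):
        """The whole flap sheet stays inside the wall circle; the deformable
        interior (away from the attachment zone, which merges with the wall)
        additionally respects the half-thickness offset up to the penalty
        resolution."""
        tol = 0.1
        t2 = 0.5 * aorta.flap.thickness
        for st in deployed_states.values():
            g = st.flap_grid.reshape(-1, 3)
            js = aorta.centerline.nearest_station(g)
            rel = g - aorta.centerline.points[js]
            x = np.einsum("ij,ij->i", rel, aorta.e1[js])
            y = np.einsum("ij,ij->i", rel, aorta.e2[js])
            r = np.hypot(x, y)
            Rw = aorta.wall_radius[js]
            assert np.all(r <= Rw + 1e-6)
            interior = np.abs(y) < Rw - t2 - 0.3
            assert np.all(r[interior] <= Rw[interior] - t2 + tol)

    def test_expanded_tl_gains_volume(self, deployed_states, aorta):
        from archstent.anatomy import lumen_volumes
        tl_pre = lumen_volumes(aorta)["TL"]
        for st in deployed_states.values():
            assert lumen_volumes(st.aorta)["TL"] > tl_pre
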