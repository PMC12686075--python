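"""Synthetic dissected-arch generator: centerlines, regions, volumes."""

import math

import numpy as np
import pytest

from archstent.anatomy import (AnatomyConfig, GenerationError,
                               build_dissected_aorta, generate_arch_centerline,
                               largest_inscribed_sphere_diameter, lumen_volumes)


class TestCenterline:
    def test_straight_tube_limit_is_collinear(self):
        cfg = AnatomyConfig(arch_radius=float("inf"), branch_positions=(),
                            branch_diameters=())
        cl = generate_arch_centerline(cfg)
        assert np.allclose(cl.tangents, cl.tangents[0])
        d = cl.points - cl.points[0]
        cross = np.cross(d[1:], cl.tangents[0])
        assert np.abs(cross).max() < 1e-9

    def test_semicircular_arch_length(self):
        R = 35.0
        cfg = AnatomyConfig(arch_radius=R, ascending_length=0.0,
                            descending_length=0.0, flap_angular_extent_deg=0,
                            branch_positions=(), branch_diameters=())
        cl = generate_arch_centerline(cfg)
        assert cl.length == pytest.approx(math.pi * R, rel=1e-3)

    def test_unit_tangents_for_various_configs(self):
        for cfg in (AnatomyConfig(), AnatomyConfig(arch_radius=25.0),
                    AnatomyConfig(ascending_length=10.0)):
            cl = generate_arch_centerline(cfg)
            assert np.abs(np.linalg.norm(cl.tangents, axis=1) - 1).max() < 1e-9

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            AnatomyConfig(arch_radius=-1.0)


class TestRegions:
    def test_no_dissection_limit(self):
        model = build_dissected_aorta(AnatomyConfig(flap_angular_extent_deg=0))
        vols = lumen_volumes(model)
        assert vols["FL"] == 0.0
        assert vols["TL"] > 0

    def test_volume_partition_closes(self, aorta):
        cs = aorta.cross_section_volumes()
        total = cs["TL"] + cs["FL"] + cs["flap"]
        assert total == pytest.approx(cs["wall_interior"], rel=0.01)

    def test_mesh_and_cross_section_volumes_agree(self, aorta):
        vols = lumen_volumes(aorta)
        cs = aorta.cross_section_volumes()
        assert vols["TL"] == pytest.approx(cs["TL"], rel=0.01)
        assert vols["FL"] == pytest.approx(cs["FL"], rel=0.01)

    def test_region_meshes_watertight(self, aorta):
        for mesh in (aorta.tl_mesh(), aorta.fl_mesh(), aorta.flap_solid_mesh(),
                     aorta.wall_interior_mesh()):
            assert mesh.is_watertight

    def test_half_split_cylinder_volumes(self):
        """Straight tube of radius 1 mm, length 10 mm, bisected by a flat
        mid-diameter flap: both lumens approach 5*pi (minus the thin flap)."""
        cfg = AnatomyConfig(arch_radius=float("inf"), ascending_length=5,
                            descending_length=5, wall_inner_diameter=2.0,
                            flap_angular_extent_deg=180, flap_axial_start=0.0,
                            flap_axial_extent=1.0, flap_taper_fraction=0.0,
                            tl_min_diameter=1.0, flap_thickness=0.02,
                            wall_thickness=0.2, branch_positions=(),
                            branch_diameters=(), surface_resolution=0.25)
        vols = lumen_volumes(build_dissected_aorta(cfg))
        half = 5 * math.pi - 0.5 * 0.02 * 2.0 * 10
        assert vols["TL"] == pytest.approx(half, rel=0.02)
        assert vols["FL"] == pytest.approx(half, rel=0.02)
        assert vols["TL"] == pytest.approx(vols["FL"], rel=0.02)

    def test_plain_cylinder_volume(self):
        cfg = AnatomyConfig(arch_radius=float("inf"), ascending_length=5,
                            descending_length=5, wall_inner_diameter=2.0,
                            flap_angular_extent_deg=0, tl_min_diameter=1.0,
                            wall_thickness=0.2, branch_positions=(),
                            branch_diameters=(), surface_resolution=0.25)
        vols = lumen_volumes(build_dissected_aorta(cfg))
        assert vols["TL"] == pytest.approx(10 * math.pi, rel=0.005)

    def test_classification_labels(self, aorta):
        # a point on the TL centerline is TL; the main-centerline point in the
        # flap region sits behind the flap, i.e. in the FL
        j = int(aorta.flap.station_indices[len(aorta.flap.station_indices) // 2])
        tl_pt = aorta.tl_centerline.points[j]
        fl_pt = aorta.centerline.points[j]
        out_pt = aorta.centerline.points[j] + 40 * aorta.e2[j]
        labels, _ = aorta.classify_points(np.stack([tl_pt, fl_pt, out_pt]))
        assert list(labels) == [1, 2, 0]

    def test_branch_points_are_fluid(self, aorta):
        b = aorta.branches[0]
        pt = b.origin + b.axis * (b.length * 0.8)
        labels, branch = aorta.classify_points(pt[None, :])
        assert labels[0] == 1 and branch[0] == 0

    def test_flap_inside_wall(self, aorta):
        g = aorta.flap.grid.reshape(-1, 3)
        st = aorta.centerline.nearest_station(g)
        rel = g - aorta.centerline.points[st]
        x = np.einsum("ij,ij->i", rel, aorta.e1[st])
        y = np.einsum("ij,ij->i", rel, aorta.e2[st])
        assert np.all(np.hypot(x, y) <= aorta.wall_radius[st] + 1e-6)

    def test_impossible_flap_raises(self):
        with pytest.raises((GenerationError, ValueError)):
            build_dissected_aorta(AnatomyConfig(tl_min_diameter=1.0,
                                                flap_thickness=2.0))


class TestInscribedSphere:
    def test_plain_cylinder_diameter(self):
        cfg = AnatomyConfig(arch_radius=float("inf"), ascending_length=20,
                            descending_length=20, wall_inner_diameter=24.0,
                            flap_angular_extent_deg=0, tl_min_diameter=12.0,
                            branch_positions=(), branch_diameters=())
        m = build_dissected_aorta(cfg)
        assert largest_inscribed_sphere_diameter(m) == pytest.approx(24.0, rel=0.02)

    def test_linear_taper_reports_narrow_end(self):
        cfg = AnatomyConfig(arch_radius=float("inf"), ascending_length=30,
                            descending_length=30, wall_inner_diameter=30.0,
                            wall_inner_diameter_distal=20.0,
                            flap_angular_extent_deg=0, tl_min_diameter=12.0,
                            branch_positions=(), branch_diameters=())
        m = build_dissected_aorta(cfg)
        assert largest_inscribed_sphere_diameter(m) == pytest.approx(20.0, rel=0.02)

    def test_default_model_matches_distance_field_oracle(self, aorta):
        """Brute-force max-min oracle: per station, densely sample candidate
        centers in the TL polygon and maximise the distance to the boundary."""
        from shapely.geometry import Point
        best = math.inf
        for j in range(0, aorta.n_stations, 3):
            poly = aorta._polygons[j]["TL"]
            if poly.is_empty:
                continue
            minx, miny, maxx, maxy = poly.bounds
            xs = np.linspace(minx, maxx, 40)
            ys = np.linspace(miny, maxy, 40)
            r_station = 0.0
            for x in xs:
                for y in ys:
                    p = Point(x, y)
                    if poly.contains(p):
                        r_station = max(r_station, poly.exterior.distance(p))
            best = min(best, 2 * r_station)
        assert largest_inscribed_sphere_diameter(aorta) == pytest.approx(
            best, rel=0.02)

    def test_configured_minimum_is_honoured(self, aorta):
        assert largest_inscribed_sphere_diameter(aorta) == pytest.approx(
            aorta.config.tl_min_diameter, rel=0.02)

    def test_centerline_outside_tl_rejected(self, aorta):
        with pytest.raises(GenerationError):
            largest_inscribed_sphere_diameter(aorta, aorta.fl_centerline)


def test_determinism_same_config_same_geometry():
    cfg = AnatomyConfig(random_seed=3)
    a = build_dissected_aorta(cfg)
    b = build_dissected_aorta(cfg)
    assert np.array_equal(a.flap.grid, b.flap.grid)
    assert np.array_equal(a.wall_surface.vertices, b.wall_surface.vertices)


def test_export_writes_products(tmp_path, aorta):
    aorta.export(tmp_path)
    for name in ("wall_surface.stl", "flap_surface.stl", "labels.json",
                 "centerline.txt", "tl_centerline.txt"):
        assert (tmp_path / name).exists()
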