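"""Crimper centerline-alignment kinematics."""

import numpy as np
import pytest

from archstent.alignment import compute_alignment_schedule
from archstent.geometry import Centerline


def _straight(n, ds, origin=(0, 0, 0), direction=(0, 0, 1)):
    d = np.asarray(direction, float)
    d /= np.linalg.norm(d)
    pts = np.asarray(origin, float) + np.outer(np.arange(n) * ds, d)
    return Centerline(pts, np.tile(d, (n, 1)))


def _oracle_states(R_pts, T, ds):
    """Independent scripted evaluation of the intermediate-state formula:
    P_i(k) = R_i for i <= k, else the straight tangent extension from R_k
    with the arc-length spacing preserved."""
    n = len(R_pts)
    states = np.empty((n, n, 3))
    for k in range(n):
        for i in range(n):
            if i <= k:
                states[k, i] = R_pts[i]
            else:
                states[k, i] = R_pts[k] + T[k] * (i - k) * ds
    return states


class TestSchedule:
    def test_already_aligned_is_the_identity(self):
        cc = _straight(10, 2.0)
        sched = compute_alignment_schedule(cc, cc)
        for k in range(sched.n_states):
            assert np.allclose(sched.centerline_states[k], cc.points)
            assert np.allclose(sched.rotation_angles[k], 0.0)

    def test_parallel_offset_is_pure_translation(self):
        cc = _straight(12, 1.5)
        c0 = _straight(12, 1.5, origin=(5.0, -3.0, 0.0))
        sched = compute_alignment_schedule(cc, c0)
        assert np.allclose(sched.rotation_angles, 0.0)
        final = sched.centerline_states[-1]
        assert np.allclose(final, c0.points)

    def test_right_angle_target_matches_scripted_oracle(self):
        """4-point right-angle target polyline: every intermediate state is
        checked against a hand-scripted evaluation of the formula (on-target
        head, straight tangent tail with preserved spacing)."""
        ds = 1.0
        R = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 1, 2], [0, 2, 2]],
                     float)
        T = np.array([[0, 0, 1], [0, 0, 1], [0, 0.70710678, 0.70710678],
                      [0, 1, 0], [0, 1, 0]])
        T = T / np.linalg.norm(T, axis=1, keepdims=True)
        c0 = Centerline(R, T)
        cc = _straight(5, ds)
        sched = compute_alignment_schedule(cc, c0)
        expect = _oracle_states(R, T, ds)
        assert np.allclose(sched.centerline_states, expect, atol=1e-12)

    def test_spacing_preserved_at_every_intermediate_state(self):
        ds = 2.5
        s = np.arange(16) * ds
        # quarter-circle target
        Rc = 16 * ds * 2 / np.pi
        phi = s / Rc
        pts = np.stack([np.zeros_like(phi), Rc * (1 - np.cos(phi)),
                        Rc * np.sin(phi)], axis=1)
        tan = np.stack([np.zeros_like(phi), np.sin(phi), np.cos(phi)], axis=1)
        c0 = Centerline(pts, tan).resample(16)
        cc = _straight(16, c0.length / 15)
        sched = compute_alignment_schedule(cc, c0)
        for k in range(sched.n_states):
            seg = np.linalg.norm(np.diff(sched.centerline_states[k][k:], axis=0),
                                 axis=1)
            if len(seg):
                assert np.allclose(seg, c0.length / 15, rtol=1e-6)

    def test_mismatched_point_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_alignment_schedule(_straight(5, 1.0), _straight(6, 1.0))

    def test_nonuniform_spacing_rejected(self):
        pts = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 3]], float)
        tan = np.tile([0, 0, 1.0], (3, 1))
        with pytest.raises(ValueError):
            compute_alignment_schedule(_straight(3, 1.0), Centerline(pts, tan))


class TestShellTransform:
    def test_cross_sections_stay_rigid_and_circular(self):
        """Shell nodes ride rigidly with their centerline point, so every
        cross-section ring keeps its radius to machine precision at every
        intermediate state."""
        n = 12
        ds = 4.0
        cc = _straight(n, ds)
        # target: half turn of a generous arc
        Rc = 2 * (n - 1) * ds / np.pi
        phi = np.arange(n) * ds / Rc
        pts = np.stack([Rc * (1 - np.cos(phi)), np.zeros_like(phi),
                        Rc * np.sin(phi)], axis=1)
        tan = np.stack([np.sin(phi), np.zeros_like(phi), np.cos(phi)], axis=1)
        c0 = Centerline(pts, tan).resample(n)
        sched = compute_alignment_schedule(cc, c0)
        radius = 9.0
        th = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        ring = np.stack([radius * np.cos(th), radius * np.sin(th),
                         np.zeros_like(th)], axis=1)
        nodes = np.concatenate([ring + cc.points[i] for i in range(n)])
        attachment = np.repeat(np.arange(n), 24)
        for k in range(0, sched.n_states, 3):
            moved = sched.transform_nodes(k, nodes, attachment)
            centers = sched.centerline_states[k][attachment]
            r = np.linalg.norm(moved - centers, axis=1)
            assert np.abs(r - radius).max() < 1e-6

    def test_anti_parallel_tangent_has_deterministic_axis(self):
        from archstent.alignment import _rotation_between
        t = np.array([0.0, 0.0, 1.0])
        axis1, ang1 = _rotation_between(t, -t, None)
        axis2, ang2 = _rotation_between(t, -t, None)
        assert ang1 == pytest.approx(np.pi)
        assert np.allclose(axis1, axis2)
        assert abs(axis1 @ t) < 1e-12
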