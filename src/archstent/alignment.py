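"""Crimper centerline-alignment kinematics.

The crimped stent is steered onto the vessel centerline by prescribing a
path for every crimper node. The crimper centerline C_c (initially straight)
is aligned to the target centerline C_0 point by point: at intermediate
state k, centerline points up to index k sit exactly on C_0 while the
remaining tail extends straight along the target tangent T_k with the
original arc-length spacing preserved,

    P_i(k) = R_i                               for i <= k
    P_i(k) = R_k + T_k * (i - k) * ds          for i >  k

Each shell node rides with its centerline point: a translation following the
point plus a rotation about a_rot,i (the normalized cross product of the old
and new local tangents) by the angle between them, which keeps every
cross-section rigid and circular throughout the motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Centerline, rotation_matrix

__all__ = ["CenterlineAlignmentSchedule", "compute_alignment_schedule"]


def _rotation_between(t_old: np.ndarray, t_new: np.ndarray,
                      prev_axis: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Axis and angle rotating unit vector t_old onto t_new.

    Degenerate cases: parallel tangents give the identity (zero angle);
    anti-parallel tangents rotate about a perpendicular axis chosen
    deterministically — the perpendicular direction maximizing the component
    magnitude of the previous rotation axis, falling back to the coordinate
    axis of largest perpendicular component.
    """
    c = float(np.clip(np.dot(t_old, t_new), -1.0, 1.0))
    axis = np.cross(t_old, t_new)
    n = np.linalg.norm(axis)
    if n > 1e-12:
        return axis / n, float(np.arctan2(n, c))
    if c > 0:
        return np.array([1.0, 0.0, 0.0]), 0.0
    # anti-parallel: any perpendicular axis works; pick deterministically
    if prev_axis is not None and np.linalg.norm(prev_axis) > 1e-12:
        cand = prev_axis - np.dot(prev_axis, t_old) * t_old
        if np.linalg.norm(cand) > 1e-12:
            return cand / np.linalg.norm(cand), np.pi
    perp = [e - np.dot(e, t_old) * t_old for e in np.eye(3)]
    norms = [np.linalg.norm(p) for p in perp]
    j = int(np.argmax(norms))
    return perp[j] / norms[j], np.pi


@dataclass
class CenterlineAlignmentSchedule:
    """Precomputed intermediate alignment states k = 0 .. n_nod - 1.

    State 0 is the initial straight configuration; state n_nod - 1 has the
    whole centerline on the target. ``centerline_states[k]`` is (n_nod, 3);
    ``rotations[k]`` is (n_nod, 3, 3) mapping initial offsets to state k.
    """

    source: Centerline
    target: Centerline
    centerline_states: np.ndarray      # (n_states, n, 3)
    rotations: np.ndarray              # (n_states, n, 3, 3)
    rotation_axes: np.ndarray          # (n_states, n, 3)
    rotation_angles: np.ndarray        # (n_states, n)

    @property
    def n_states(self) -> int:
        return len(self.centerline_states)

    def transform_nodes(self, k: int, nodes: np.ndarray,
                        attachment: np.ndarray) -> np.ndarray:
        """Move shell nodes to state k.

        nodes: initial node positions (m, 3); attachment: index of the
        centerline point each node rides with (m,). The node keeps its rigid
        offset from that point, rotated by the local tangent rotation.
        """
        offs = nodes - self.source.points[attachment]
        R = self.rotations[k][attachment]
        return self.centerline_states[k][attachment] \
            + np.einsum("nij,nj->ni", R, offs)

    def node_paths(self, nodes: np.ndarray, attachment: np.ndarray) -> np.ndarray:
        """Full per-node path through all states: (n_states, m, 3)."""
        return np.array([self.transform_nodes(k, nodes, attachment)
                         for k in range(self.n_states)])


def compute_alignment_schedule(C_c: Centerline, C_0: Centerline) -> CenterlineAlignmentSchedule:
    """Schedule aligning the crimper centerline C_c with the vessel centerline C_0.

    Both polylines must have the same number of points and the same uniform
    arc-length spacing; the tail spacing |P_{m+1} - P_m| is preserved at
    every intermediate state.
    """
    n = len(C_c)
    if len(C_0) != n:
        raise ValueError("centerlines must have equal point counts")
    ds_c, ds_0 = C_c.spacing, C_0.spacing
    ds = float(np.mean(ds_0))
    if np.any(np.abs(ds_c - ds) > 1e-3 * ds) or np.any(np.abs(ds_0 - ds) > 1e-3 * ds):
        raise ValueError("centerlines must share a uniform arc-length spacing")

    R_pts, T = C_0.points, C_0.tangents
    t_old = C_c.tangents
    states = np.empty((n, n, 3))
    rots = np.empty((n, n, 3, 3))
    axes = np.zeros((n, n, 3))
    angles = np.zeros((n, n))
    idx = np.arange(n)
    prev_axis = [None] * n
    for k in range(n):
        on = idx <= k
        states[k][on] = R_pts[idx[on]]
        states[k][~on] = R_pts[k] + np.outer((idx[~on] - k) * ds, T[k])
        t_new = np.where(on[:, None], T[idx], T[k][None, :])
        for i in range(n):
            a, phi = _rotation_between(t_old[i], t_new[i], prev_axis[i])
            axes[k, i] = a
            angles[k, i] = phi
            rots[k, i] = rotation_matrix(a, phi)
            prev_axis[i] = a
    return CenterlineAlignmentSchedule(C_c, C_0, states, rots, axes, angles)
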