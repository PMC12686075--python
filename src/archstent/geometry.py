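"""Centerline polylines, transported frames and loft-mesh helpers.

Coordinates are millimetres, right-handed. A centerline is an ordered 3D
polyline with unit tangents and strictly increasing cumulative arc length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Centerline", "rotation_matrix", "parallel_transport_frames", "loft_closed_loops"]


@dataclass(frozen=True)
class Centerline:
    """Ordered polyline with per-point unit tangents and cumulative arc length [mm]."""

    points: np.ndarray            # (n, 3)
    tangents: np.ndarray          # (n, 3) unit vectors
    arclength: np.ndarray = field(default=None)  # (n,) cumulative, starts at 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        tan = np.asarray(self.tangents, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ValueError("centerline needs >= 2 points of shape (n, 3)")
        if tan.shape != pts.shape:
            raise ValueError("tangents must match points in shape")
        norms = np.linalg.norm(tan, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("tangents must have unit norm (within 1e-9)")
        if self.arclength is None:
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            s = np.concatenate([[0.0], np.cumsum(seg)])
            object.__setattr__(self, "arclength", s)
        s = np.asarray(self.arclength, dtype=float)
        if np.any(np.diff(s) <= 0):
            raise ValueError("cumulative arc length must be strictly increasing")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "tangents", tan)
        object.__setattr__(self, "arclength", s)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    @property
    def spacing(self) -> np.ndarray:
        return np.diff(self.arclength)

    def point_at(self, s) -> np.ndarray:
        """Linear interpolation of position at arc length(s) s."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        out = np.empty(np.shape(s) + (3,))
        for k in range(3):
            out[..., k] = np.interp(s, self.arclength, self.points[:, k])
        return out

    def tangent_at(self, s) -> np.ndarray:
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        out = np.empty(np.shape(s) + (3,))
        for k in range(3):
            out[..., k] = np.interp(s, self.arclength, self.tangents[:, k])
        n = np.linalg.norm(out, axis=-1, keepdims=True)
        return out / n

    def resample(self, n: int) -> "Centerline":
        """Uniform arc-length resampling to n points (tangents re-normalised)."""
        s = np.linspace(0.0, self.length, n)
        return Centerline(self.point_at(s), self.tangent_at(s), s)

    def nearest_station(self, pts: np.ndarray) -> np.ndarray:
        """Index of the nearest centerline point for each query point."""
        from scipy.spatial import cKDTree
        pts = np.atleast_2d(pts)
        return cKDTree(self.points).query(pts)[1]


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-14 or abs(angle) < 1e-15:
        return np.eye(3)
    a = axis / n
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def parallel_transport_frames(cl: Centerline, e1_start: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-minimising frames (e1, e2) along a centerline.

    e1_start is projected perpendicular to the first tangent and then
    transported by the minimal rotation mapping each tangent to the next.
    """
    t = cl.tangents
    e1 = np.empty_like(t)
    v = np.asarray(e1_start, dtype=float)
    v = v - np.dot(v, t[0]) * t[0]
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise ValueError("e1_start is parallel to the first tangent")
    e1[0] = v / nv
    for i in range(1, len(t)):
        axis = np.cross(t[i - 1], t[i])
        s = np.linalg.norm(axis)
        c = float(np.clip(np.dot(t[i - 1], t[i]), -1.0, 1.0))
        if s < 1e-14:
            e1[i] = e1[i - 1]
        else:
            R = rotation_matrix(axis / s, np.arctan2(s, c))
            e1[i] = R @ e1[i - 1]
        # re-orthogonalise against drift
        e1[i] -= np.dot(e1[i], t[i]) * t[i]
        e1[i] /= np.linalg.norm(e1[i])
    e2 = np.cross(t, e1)
    return e1, e2


def loft_closed_loops(loops: np.ndarray,
                      cap_start: np.ndarray | None = None,
                      cap_end: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate a tube through a stack of closed loops of equal vertex count.

    loops: (n_stations, n_loop, 3); loop vertices ordered consistently, the
    loop is closed implicitly (last vertex connects back to the first).
    cap_start / cap_end: apex point (3,) to fan-close that end; ``None``
    closes with a fan from the loop centroid (flat cap).

    Returns (vertices, faces) with outward orientation left to the caller's
    loop ordering.
    """
    loops = np.asarray(loops, dtype=float)
    ns, nl, _ = loops.shape
    verts = [loops.reshape(-1, 3)]
    faces = []
    idx = np.arange(nl)
    nxt = np.roll(idx, -1)
    for j in range(ns - 1):
        a = j * nl + idx
        b = j * nl + nxt
        c = (j + 1) * nl + idx
        d = (j + 1) * nl + nxt
        faces.append(np.stack([a, b, d], axis=1))
        faces.append(np.stack([a, d, c], axis=1))
    n_base = ns * nl

    def _cap(loop_row: int, apex: np.ndarray | None, flip: bool) -> None:
        nonlocal n_base
        apex_pt = np.mean(loops[loop_row], axis=0) if apex is None else np.asarray(apex, float)
        verts.append(apex_pt[None, :])
        ai = n_base
        n_base += 1
        a = loop_row * nl + idx
        b = loop_row * nl + nxt
        tri = np.stack([b, a, np.full(nl, ai)], axis=1) if not flip else \
            np.stack([a, b, np.full(nl, ai)], axis=1)
        faces.append(tri)

    _cap(0, cap_start, flip=False)
    _cap(ns - 1, cap_end, flip=True)
    return np.concatenate(verts, axis=0), np.concatenate(faces, axis=0)
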