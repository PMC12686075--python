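"""Parametric synthetic anatomy: a dissected aortic arch with true/false lumen.

The generator stands in for a patient-specific segmentation. It produces a
curved aortic arch (straight ascending segment, circular arch, straight
descending segment) with three branch vessels on the outer curvature, and a
dissection flap that separates a narrowed true lumen (TL, inner-curvature
side by default) from a false lumen (FL) from the distal arch into the
descending aorta. The proximal ascending segment is left undissected,
emulating a post-hemiarch repair.

Cross-section model
-------------------
In every cross-section plane (local frame ``e1`` toward the arch center,
``e2`` completing the right-handed frame) the wall is a circle of radius
``Rw``. Where the flap is present it is a circular arc chord attached to the
wall at angles ``±theta_att`` about ``e1``, bowing to an apex on the ``e1``
axis. The region between flap and near wall arc is the TL, the pocket behind
the flap is the FL. The flap tapers (pinches onto the wall) at both axial
ends so the FL closes smoothly. All region measures (areas, volumes,
inscribed diameters) are evaluated on these cross-sections and, for the
closed-surface route, on lofted triangle meshes.

Units: mm throughout; volumes mm^3.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
import trimesh
from shapely.geometry import Point, Polygon
from shapely.ops import polylabel

from .geometry import Centerline, loft_closed_loops, parallel_transport_frames

__all__ = [
    "AnatomyConfig",
    "Branch",
    "CutPlane",
    "DissectedAortaModel",
    "GenerationError",
    "generate_arch_centerline",
    "build_dissected_aorta",
    "lumen_volumes",
    "largest_inscribed_sphere_diameter",
]


class GenerationError(RuntimeError):
    """Raised when a requested anatomy cannot be generated consistently."""


def _largest(geom) -> Polygon:
    """Largest polygonal component of a shapely geometry."""
    if isinstance(geom, Polygon):
        return geom
    polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    if not polys:
        return Polygon()
    return max(polys, key=lambda g: g.area)


@dataclass(frozen=True)
class AnatomyConfig:
    """Parameters of the synthetic dissected arch (all lengths in mm).

    ``arch_radius = inf`` is the zero-curvature flag: the model degenerates
    to a straight tube of length ascending + descending.
    """

    arch_radius: float = 40.0
    ascending_length: float = 60.0
    descending_length: float = 120.0
    wall_inner_diameter: float = 30.0
    wall_inner_diameter_distal: float | None = None  # linear taper if set
    wall_thickness: float = 2.0
    flap_thickness: float = 2.0
    flap_angular_extent_deg: float = 160.0
    flap_axial_start: float = 0.45          # fraction of centerline length
    flap_axial_extent: float = 0.20         # fraction of centerline length
    flap_taper_fraction: float = 0.20       # fraction of flap span per pinch ramp
    tl_min_diameter: float = 12.0
    branch_positions: Sequence[float] = (0.24, 0.31, 0.38)  # centerline fractions
    branch_diameters: Sequence[float] = (10.0, 8.0, 8.0)
    branch_length: float = 25.0
    surface_resolution: float = 2.5         # target station spacing / edge length
    n_flap_samples: int = 15                # cross-section samples across the flap
    n_arc_samples: int = 48                 # cross-section samples on the wall arc
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not self.arch_radius > 0:
            raise ValueError("arch_radius must be positive (inf for a straight tube)")
        for name in ("ascending_length", "descending_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("wall_inner_diameter", "wall_thickness", "flap_thickness",
                     "surface_resolution", "branch_length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.flap_axial_extent <= 1:
            raise ValueError("flap_axial_extent must be in (0, 1]")
        if not 0 <= self.flap_axial_start < 1:
            raise ValueError("flap_axial_start must be in [0, 1)")
        if self.flap_axial_start + self.flap_axial_extent > 1 + 1e-12:
            raise ValueError("flap extends past the end of the centerline")
        if not 0 <= self.flap_angular_extent_deg < 360:
            raise ValueError("flap_angular_extent_deg must be in [0, 360)")
        if not self.tl_min_diameter < self.wall_inner_diameter:
            raise ValueError("TL minimum diameter must be smaller than the wall diameter")
        if self.has_flap and not self.tl_min_diameter > self.flap_thickness:
            raise ValueError("TL minimum diameter must exceed the flap thickness")
        if len(self.branch_positions) != len(self.branch_diameters):
            raise ValueError("branch positions and diameters must have equal length")
        if not 0 <= self.flap_taper_fraction < 0.5:
            raise ValueError("flap_taper_fraction must be in [0, 0.5)")

    @property
    def has_flap(self) -> bool:
        return self.flap_angular_extent_deg > 0 and self.flap_axial_extent > 0

    @property
    def total_length(self) -> float:
        arch = 0.0 if math.isinf(self.arch_radius) else math.pi * self.arch_radius
        return self.ascending_length + arch + self.descending_length


@dataclass(frozen=True)
class Branch:
    """Straight branch vessel on the outer curvature of the arch."""

    name: str
    origin: np.ndarray       # centerline point (3,)
    axis: np.ndarray         # unit direction, points away from the lumen
    radius: float
    length: float            # measured from the centerline point
    station: int


@dataclass(frozen=True)
class CutPlane:
    name: str
    origin: np.ndarray
    normal: np.ndarray


def generate_arch_centerline(config: AnatomyConfig) -> Centerline:
    """Ascending / circular-arch / descending centerline at uniform spacing.

    The curve lies in the x-z plane: ascending along +z from the origin
    (aortic root), a semicircular arch of radius ``arch_radius`` turning into
    -z, then the straight descending segment. ``arch_radius = inf`` yields a
    straight tube (collinear points, identical tangents).
    """
    La, Ld, Ra = config.ascending_length, config.descending_length, config.arch_radius
    L = config.total_length
    if L <= 0:
        raise ValueError("centerline has zero length")
    n = max(int(round(L / config.surface_resolution)) + 1, 8)
    s = np.linspace(0.0, L, n)
    pts = np.zeros((n, 3))
    tan = np.zeros((n, 3))
    if math.isinf(Ra):
        pts[:, 2] = s
        tan[:, 2] = 1.0
        return Centerline(pts, tan, s)
    arch_len = math.pi * Ra
    for i, si in enumerate(s):
        if si <= La:
            pts[i] = (0.0, 0.0, si)
            tan[i] = (0.0, 0.0, 1.0)
        elif si <= La + arch_len:
            phi = (si - La) / Ra
            pts[i] = (Ra * (1.0 - math.cos(phi)), 0.0, La + Ra * math.sin(phi))
            tan[i] = (math.sin(phi), 0.0, math.cos(phi))
        else:
            pts[i] = (2.0 * Ra, 0.0, La - (si - La - arch_len))
            tan[i] = (0.0, 0.0, -1.0)
    return Centerline(pts, tan, s)


def _smooth_window(u: np.ndarray, taper: float) -> np.ndarray:
    """C1 pinch window on [0, 1]: 0 at both ends, 1 on the plateau."""
    if taper <= 0:
        return np.ones_like(u)
    w = np.ones_like(u)
    lo = u < taper
    hi = u > 1.0 - taper
    w[lo] = np.sin(0.5 * np.pi * u[lo] / taper) ** 2
    w[hi] = np.sin(0.5 * np.pi * (1.0 - u[hi]) / taper) ** 2
    return w


def _flap_arc_2d(theta_att: float, apex_x: float, Rw: float, n_u: int) -> np.ndarray:
    """Circular-arc flap cross-section from attachment A (+y) to B (-y).

    Returns (n_u, 2) points including both attachment points, passing through
    the apex (apex_x, 0). Falls back to a straight chord when collinear.
    """
    A = np.array([Rw * math.cos(theta_att), Rw * math.sin(theta_att)])
    B = np.array([A[0], -A[1]])
    if abs(A[0] - apex_x) < 1e-9 or A[1] < 1e-9:
        t = np.linspace(0.0, 1.0, n_u)[:, None]
        return A[None, :] * (1 - t) + B[None, :] * t
    xc = (Rw * Rw - apex_x * apex_x) / (2.0 * (A[0] - apex_x))
    rc = abs(apex_x - xc)
    psi = math.atan2(A[1], A[0] - xc)
    if apex_x > xc:  # apex at local angle 0, sweep through it
        phi = np.linspace(psi, -psi, n_u)
    else:            # apex at local angle pi
        psi = psi if psi > 0 else psi + 2.0 * math.pi
        phi = np.linspace(psi, 2.0 * math.pi - psi, n_u)
    return np.stack([xc + rc * np.cos(phi), rc * np.sin(phi)], axis=1)


def _offset_curve(curve: np.ndarray, offset: float, Rw: float) -> np.ndarray:
    """Offset a 2D polyline along its in-plane normal toward the TL (+offset).

    The normal is oriented so that positive offsets move toward larger x
    at the apex (the TL side). Points are clamped inside the wall circle.
    """
    d = np.gradient(curve, axis=0)
    nrm = np.stack([d[:, 1], -d[:, 0]], axis=1)
    ln = np.linalg.norm(nrm, axis=1, keepdims=True)
    ln[ln < 1e-12] = 1.0
    nrm /= ln
    # orient toward +x at the mid point
    mid = len(curve) // 2
    if nrm[mid, 0] < 0:
        nrm = -nrm
    out = curve + offset * nrm
    r = np.linalg.norm(out, axis=1)
    over = r > Rw
    if np.any(over):
        out[over] *= (Rw / r[over])[:, None]
    return out


@dataclass
class FlapSheet:
    """Discrete flap mid-surface: one polyline row per axial station."""

    station_indices: np.ndarray      # (n_fs,) indices into the model stations
    grid: np.ndarray                 # (n_fs, n_u, 3) mid-surface points
    thickness: float
    pinch_window: np.ndarray         # (n_fs,) taper window value per row


class DissectedAortaModel:
    """Labeled synthetic dissected-arch model.

    Holds the centerline, transported frames, the per-station wall radius,
    the discrete flap sheet, branch vessels and cut planes, and derives all
    region quantities (polygons, volumes, centerlines, meshes) from them.
    Instances are treated as immutable; ``with_flap_grid`` returns a new
    model carrying a deformed flap.
    """

    def __init__(self, config: AnatomyConfig, centerline: Centerline,
                 e1: np.ndarray, e2: np.ndarray, kappa: np.ndarray,
                 wall_radius: np.ndarray, flap: FlapSheet | None,
                 branches: list[Branch]):
        self.config = config
        self.centerline = centerline
        self.e1 = e1
        self.e2 = e2
        self.kappa = kappa
        self.wall_radius = np.asarray(wall_radius, dtype=float)
        self.flap = flap
        self.branches = branches

    # ---------------------------------------------------------------- frames
    @property
    def n_stations(self) -> int:
        return len(self.centerline)

    def to_frame(self, station: int, pts: np.ndarray) -> np.ndarray:
        """Project 3D points into the (e1, e2) coordinates of a station plane."""
        rel = np.atleast_2d(pts) - self.centerline.points[station]
        return np.stack([rel @ self.e1[station], rel @ self.e2[station]], axis=1)

    def from_frame(self, station: int, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return (self.centerline.points[station]
                + np.outer(xy[:, 0], self.e1[station])
                + np.outer(xy[:, 1], self.e2[station]))

    @property
    def cut_planes(self) -> list[CutPlane]:
        cl = self.centerline
        planes = [
            CutPlane("inlet", cl.points[0], -cl.tangents[0]),
            CutPlane("outlet", cl.points[-1], cl.tangents[-1]),
        ]
        for b in self.branches:
            planes.append(CutPlane(f"outlet_{b.name}", b.origin + b.axis * b.length, b.axis))
        return planes

    # ------------------------------------------------------- cross-sections
    def flap_rows_2d(self) -> dict[int, np.ndarray]:
        """Flap mid-surface polyline per station, in frame coordinates."""
        if self.flap is None:
            return {}
        out = {}
        for r, j in enumerate(self.flap.station_indices):
            out[int(j)] = self.to_frame(int(j), self.flap.grid[r])
        return out

    @cached_property
    def _flap_2d(self) -> dict[int, np.ndarray]:
        return self.flap_rows_2d()

    def _wall_arc(self, station: int, th0: float, th1: float, n: int) -> np.ndarray:
        th = np.linspace(th0, th1, n)
        Rw = self.wall_radius[station]
        return np.stack([Rw * np.cos(th), Rw * np.sin(th)], axis=1)

    def _attachment_angle(self, station: int) -> float:
        """Angle about +e1 of the flap attachment points at a station."""
        cur = self._flap_2d[station]
        return math.atan2(abs(cur[0, 1]), cur[0, 0])

    def cross_section_polygons(self, station: int) -> dict[str, Polygon]:
        """Shapely polygons of the TL, FL and flap solid in a station plane."""
        cfg = self.config
        Rw = self.wall_radius[station]
        n_arc = cfg.n_arc_samples
        if station not in self._flap_2d:
            circ = self._wall_arc(station, -math.pi, math.pi * (1 - 2.0 / n_arc), n_arc)
            return {"TL": Polygon(circ), "FL": Polygon(), "flap": Polygon()}
        cur = self._flap_2d[station]
        t2 = 0.5 * self.flap.thickness
        tl_face = _offset_curve(cur, +t2, Rw)
        fl_face = _offset_curve(cur, -t2, Rw)
        th = self._attachment_angle(station)
        if th < 1e-6 or abs(cur[0, 1]) < 1e-9:   # pinched row: no FL here
            circ = self._wall_arc(station, -math.pi, math.pi * (1 - 2.0 / n_arc), n_arc)
            return {"TL": Polygon(circ), "FL": Polygon(), "flap": Polygon()}
        near = self._wall_arc(station, -th, th, n_arc)
        far = self._wall_arc(station, th, 2.0 * math.pi - th, n_arc)
        disk = Point(0, 0).buffer(Rw, quad_segs=64)
        # near arc runs B -> A, the flap curves run A -> B
        tl = _largest(Polygon(np.concatenate([near, tl_face])).buffer(0).intersection(disk))
        fl = _largest(Polygon(np.concatenate([far, fl_face[::-1]])).buffer(0).intersection(disk))
        fp = _largest(Polygon(np.concatenate([tl_face, fl_face[::-1]])).buffer(0).intersection(disk))
        return {"TL": tl, "FL": fl, "flap": fp}

    @cached_property
    def _polygons(self) -> list[dict[str, Polygon]]:
        return [self.cross_section_polygons(i) for i in range(self.n_stations)]

    def cross_section_volumes(self) -> dict[str, float]:
        """Region volumes by integrating cross-section areas along the arc.

        Uses the exact curved-tube Jacobian (1 - kappa * x_e1): material at
        the inner curvature sweeps a shorter path through the arch.
        """
        s = self.centerline.arclength
        vals = {"TL": np.zeros(self.n_stations), "FL": np.zeros(self.n_stations),
                "flap": np.zeros(self.n_stations), "wall_interior": np.zeros(self.n_stations)}
        for i, polys in enumerate(self._polygons):
            Rw = self.wall_radius[i]
            for key in ("TL", "FL", "flap"):
                p = polys[key]
                if p.is_empty or p.area <= 0:
                    continue
                c = p.centroid
                vals[key][i] = p.area * (1.0 - self.kappa[i] * c.x)
            vals["wall_interior"][i] = math.pi * Rw * Rw
        return {k: float(np.trapezoid(v, s)) for k, v in vals.items()}

    # ------------------------------------------------------- centerlines
    def _region_centers(self, key: str) -> np.ndarray:
        centers = np.zeros((self.n_stations, 2))
        for i, polys in enumerate(self._polygons):
            p = polys[key]
            if p.is_empty or p.area <= 0:
                centers[i] = np.nan
                continue
            if key == "TL" and i not in self._flap_2d:
                centers[i] = 0.0
                continue
            lbl = polylabel(p, tolerance=0.05)
            centers[i] = (lbl.x, lbl.y)
        return centers

    def _region_centerline(self, key: str) -> Centerline:
        centers = self._region_centers(key)
        ok = ~np.isnan(centers[:, 0])
        idx = np.where(ok)[0]
        if len(idx) < 2:
            raise GenerationError(f"region {key!r} has no extended centerline")
        pts = np.array([self.from_frame(int(i), centers[i][None, :])[0] for i in idx])
        # light smoothing to remove pole-of-inaccessibility jitter
        if len(pts) > 4:
            sm = pts.copy()
            sm[1:-1] = (pts[:-2] + 2 * pts[1:-1] + pts[2:]) / 4.0
            pts = sm
        tan = np.gradient(pts, axis=0)
        tan /= np.linalg.norm(tan, axis=1, keepdims=True)
        return Centerline(pts, tan)

    @cached_property
    def tl_centerline(self) -> Centerline:
        """Path of the per-station maximum-inscribed-circle centers of the TL."""
        return self._region_centerline("TL")

    @cached_property
    def fl_centerline(self) -> Centerline:
        return self._region_centerline("FL")

    # ------------------------------------------------------------- meshes
    def _tl_loops(self, face_offset: float) -> np.ndarray:
        cfg = self.config
        n_arc, n_u = cfg.n_arc_samples, cfg.n_flap_samples
        loops = np.empty((self.n_stations, n_arc + n_u, 3))
        for i in range(self.n_stations):
            Rw = self.wall_radius[i]
            raw = self._flap_2d.get(i)
            if raw is not None and abs(raw[0, 1]) > 1e-9 \
                    and self._attachment_angle(i) < math.pi - 1e-6:
                th = self._attachment_angle(i)
                arc = self._wall_arc(i, -th, th, n_arc)
                cur = _offset_curve(raw, face_offset, Rw)
                interior = cur[1:-1]
                # resample flap interior to n_u points (A -> B order)
                t = np.linspace(0, 1, len(interior))
                ti = np.linspace(0, 1, n_u)
                flap_pts = np.stack([np.interp(ti, t, interior[:, 0]),
                                     np.interp(ti, t, interior[:, 1])], axis=1)
                loop2d = np.concatenate([arc, flap_pts])
            else:
                th = np.linspace(-math.pi, math.pi, n_arc + n_u, endpoint=False)
                loop2d = np.stack([Rw * np.cos(th), Rw * np.sin(th)], axis=1)
            loops[i] = self.from_frame(i, loop2d)
        return loops

    def wall_interior_mesh(self) -> trimesh.Trimesh:
        n = self.config.n_arc_samples + self.config.n_flap_samples
        loops = np.empty((self.n_stations, n, 3))
        for i in range(self.n_stations):
            th = np.linspace(-math.pi, math.pi, n, endpoint=False)
            xy = np.stack([self.wall_radius[i] * np.cos(th),
                           self.wall_radius[i] * np.sin(th)], axis=1)
            loops[i] = self.from_frame(i, xy)
        v, f = loft_closed_loops(loops)
        return _as_volume_mesh(v, f)

    @property
    def wall_surface(self) -> trimesh.Trimesh:
        """Closed inner wall surface (the lumen boundary, branches omitted)."""
        return self.wall_interior_mesh()

    @property
    def flap_surface(self) -> trimesh.Trimesh:
        """Flap mid-surface sheet (open mesh, attached edges on the wall)."""
        if self.flap is None:
            return trimesh.Trimesh()
        g = self.flap.grid
        nf, nu, _ = g.shape
        faces = []
        for i in range(nf - 1):
            for j in range(nu - 1):
                a = i * nu + j
                faces.append([a, a + 1, a + nu + 1])
                faces.append([a, a + nu + 1, a + nu])
        return trimesh.Trimesh(g.reshape(-1, 3), np.array(faces), process=False)

    def tl_mesh(self) -> trimesh.Trimesh:
        t2 = 0.5 * self.flap.thickness if self.flap is not None else 0.0
        v, f = loft_closed_loops(self._tl_loops(+t2))
        return _as_volume_mesh(v, f)

    def fl_mesh(self) -> trimesh.Trimesh:
        if self.flap is None:
            return trimesh.Trimesh()
        cfg = self.config
        n_arc, n_u = cfg.n_arc_samples, cfg.n_flap_samples
        rows = [int(j) for j in self.flap.station_indices]
        loops = []
        for i in rows:
            Rw = self.wall_radius[i]
            th = self._attachment_angle(i)
            th = max(th, 1e-4)
            far = self._wall_arc(i, th, 2.0 * math.pi - th, n_arc)
            cur = _offset_curve(self._flap_2d[i], -0.5 * self.flap.thickness, Rw)
            t = np.linspace(0, 1, len(cur))
            ti = np.linspace(0, 1, n_u + 2)[1:-1]
            flap_pts = np.stack([np.interp(ti, t, cur[:, 0]),
                                 np.interp(ti, t, cur[:, 1])], axis=1)
            loop2d = np.concatenate([far, flap_pts[::-1]])
            loops.append(self.from_frame(i, loop2d))
        v, f = loft_closed_loops(np.array(loops))
        return _as_volume_mesh(v, f)

    def flap_solid_mesh(self) -> trimesh.Trimesh:
        if self.flap is None:
            return trimesh.Trimesh()
        rows = [int(j) for j in self.flap.station_indices]
        top, bot = [], []
        for r, i in enumerate(rows):
            Rw = self.wall_radius[i]
            cur = self._flap_2d[i]
            top.append(self.from_frame(i, _offset_curve(cur, +0.5 * self.flap.thickness, Rw)))
            bot.append(self.from_frame(i, _offset_curve(cur, -0.5 * self.flap.thickness, Rw)))
        top = np.array(top)
        bot = np.array(bot)
        nf, nu, _ = top.shape
        verts = np.concatenate([top.reshape(-1, 3), bot.reshape(-1, 3)])
        off = nf * nu
        faces = []
        for i in range(nf - 1):
            for j in range(nu - 1):
                a = i * nu + j
                faces += [[a, a + nu + 1, a + 1], [a, a + nu, a + nu + 1]]
                b = off + a
                faces += [[b, b + 1, b + nu + 1], [b, b + nu + 1, b + nu]]
        for i in range(nf - 1):          # attachment edge strips
            for j in (0, nu - 1):
                a, b = i * nu + j, (i + 1) * nu + j
                if j == 0:
                    faces += [[a, b, off + b], [a, off + b, off + a]]
                else:
                    faces += [[a, off + b, b], [a, off + a, off + b]]
        for j in range(nu - 1):          # axial end strips
            a, b = j, j + 1
            faces += [[a, off + a, b], [b, off + a, off + b]]
            a, b = (nf - 1) * nu + j, (nf - 1) * nu + j + 1
            faces += [[a, b, off + a], [b, off + b, off + a]]
        return _as_volume_mesh(verts, np.array(faces))

    # ------------------------------------------------------- classification
    def classify_points(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Label 3D points: 0 outside, 1 TL, 2 FL, 3 flap solid.

        Returns (labels, branch_id) where branch_id >= 0 marks points inside
        a branch vessel (labelled TL, as branches take off proximal to the
        dissection) and -1 elsewhere.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        labels = np.zeros(len(pts), dtype=np.int8)
        branch_id = np.full(len(pts), -1, dtype=np.int16)
        station = self.centerline.nearest_station(pts)
        # points beyond the inlet/outlet cut planes are outside the lumen;
        # the test is local to the tube ends (the arch itself may bend back
        # past the inlet plane)
        cl = self.centerline
        n = self.n_stations
        d0 = (pts - cl.points[0]) @ cl.tangents[0]
        d1 = (pts - cl.points[-1]) @ cl.tangents[-1]
        beyond = ((station <= 2) & (d0 < -1e-9)) \
            | ((station >= n - 3) & (d1 > 1e-9))
        station = np.where(beyond, -1, station)
        for i in np.unique(station):
            if i < 0:
                continue
            sel = np.where(station == i)[0]
            xy = self.to_frame(int(i), pts[sel])
            r2 = (xy ** 2).sum(axis=1)
            inside = r2 < self.wall_radius[i] ** 2
            if int(i) in self._flap_2d and self._attachment_angle(int(i)) > 1e-6:
                polys = self._polygons[int(i)]
                in_tl = shapely.contains_xy(polys["TL"], xy[:, 0], xy[:, 1])
                in_fl = shapely.contains_xy(polys["FL"], xy[:, 0], xy[:, 1]) if not polys["FL"].is_empty \
                    else np.zeros(len(xy), bool)
                lab = np.where(in_tl, 1, np.where(in_fl, 2, 3)).astype(np.int8)
                lab[~inside] = 0
                labels[sel] = lab
            else:
                labels[sel] = np.where(inside, 1, 0).astype(np.int8)
        # branch vessels (outside the main lumen)
        for k, b in enumerate(self.branches):
            rel = pts - b.origin
            a = rel @ b.axis
            rad2 = (rel - np.outer(a, b.axis))
            rad2 = (rad2 ** 2).sum(axis=1)
            inb = (a > 0) & (a <= b.length) & (rad2 < b.radius ** 2)
            newly = inb & (labels == 0)
            labels[newly] = 1
            branch_id[inb] = k
        return labels, branch_id

    def with_flap_grid(self, grid: np.ndarray) -> "DissectedAortaModel":
        """New model with a deformed flap mid-surface (same topology)."""
        if self.flap is None:
            raise ValueError("model has no flap")
        flap = FlapSheet(self.flap.station_indices, np.asarray(grid, float),
                         self.flap.thickness, self.flap.pinch_window)
        return DissectedAortaModel(self.config, self.centerline, self.e1, self.e2,
                                   self.kappa, self.wall_radius, flap, self.branches)

    # ------------------------------------------------------------- export
    def export(self, outdir: str | Path) -> None:
        """Write STL surfaces, label sidecar and centerlines as plain text."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.wall_surface.export(outdir / "wall_surface.stl")
        if self.flap is not None:
            self.flap_surface.export(outdir / "flap_surface.stl")
        labels = {
            "surfaces": {"wall_surface.stl": "wall", "flap_surface.stl": "flap"},
            "regions": {"TL": "true lumen", "FL": "false lumen"},
            "volumes_mm3": lumen_volumes(self),
            "branches": [b.name for b in self.branches],
        }
        (outdir / "labels.json").write_text(json.dumps(labels, indent=2))
        for name, cl in (("centerline", self.centerline), ("tl_centerline", self.tl_centerline)):
            np.savetxt(outdir / f"{name}.txt", cl.points, fmt="%.6f")


def _as_volume_mesh(vertices: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    m = trimesh.Trimesh(vertices, faces, process=True, validate=True)
    m.merge_vertices()
    m.update_faces(m.nondegenerate_faces())
    m.remove_unreferenced_vertices()
    if m.volume < 0:
        m.invert()
    return m


def build_dissected_aorta(config: AnatomyConfig) -> DissectedAortaModel:
    """Assemble the labeled dissected-arch model from its configuration."""
    cl = generate_arch_centerline(config)
    e1, e2 = parallel_transport_frames(cl, np.array([1.0, 0.0, 0.0]))
    s = cl.arclength
    L = cl.length
    kappa = np.zeros(len(cl))
    if not math.isinf(config.arch_radius):
        on_arch = (s > config.ascending_length) & (s < config.ascending_length
                                                   + math.pi * config.arch_radius)
        kappa[on_arch] = 1.0 / config.arch_radius
    Rw0 = 0.5 * config.wall_inner_diameter
    if config.wall_inner_diameter_distal is not None:
        Rw1 = 0.5 * config.wall_inner_diameter_distal
        wall_radius = Rw0 + (Rw1 - Rw0) * (s / L)
    else:
        wall_radius = np.full(len(cl), Rw0)

    flap = None
    if config.has_flap:
        f0, f1 = config.flap_axial_start, config.flap_axial_start + config.flap_axial_extent
        rows = np.where((s >= f0 * L - 1e-9) & (s <= f1 * L + 1e-9))[0]
        if len(rows) < 4:
            raise GenerationError("flap axial extent too short for the station spacing")
        u = (s[rows] - f0 * L) / max((f1 - f0) * L, 1e-9)
        w = _smooth_window(u, config.flap_taper_fraction)
        theta_half = math.radians(config.flap_angular_extent_deg) / 2.0
        n_u = config.n_flap_samples
        grid = np.empty((len(rows), n_u, 3))
        for r, j in enumerate(rows):
            Rw = wall_radius[j]
            # mid-surface apex; the TL face sits half a thickness closer to the
            # wall, so the open TL channel is exactly tl_min_diameter wide
            apex_open = Rw - config.tl_min_diameter - 0.5 * config.flap_thickness
            if apex_open + 0.5 * config.flap_thickness >= Rw - 1e-9:
                raise GenerationError("flap apex reaches the wall; reduce flap thickness "
                                      "or increase the TL minimum diameter")
            th_att = math.pi - (math.pi - theta_half) * w[r]
            apex_x = -Rw + (apex_open + Rw) * w[r]
            cur = _flap_arc_2d(th_att, apex_x, Rw, n_u)
            if np.any(np.linalg.norm(cur, axis=1) > Rw + 1e-6):
                raise GenerationError("flap cross-section escapes the wall circle")
            grid[r] = (cl.points[j][None, :]
                       + np.outer(cur[:, 0], e1[j]) + np.outer(cur[:, 1], e2[j]))
        flap = FlapSheet(rows, grid, config.flap_thickness, w)

    branches = []
    names = ("brachiocephalic", "left_carotid", "left_subclavian")
    for k, (frac, dia) in enumerate(zip(config.branch_positions, config.branch_diameters)):
        j = int(np.argmin(np.abs(s - frac * L)))
        axis = -e1[j]
        name = names[k] if k < len(names) else f"branch_{k}"
        branches.append(Branch(name, cl.points[j], axis, 0.5 * dia,
                               wall_radius[j] + config.branch_length, j))

    model = DissectedAortaModel(config, cl, e1, e2, kappa, wall_radius, flap, branches)
    return model


def lumen_volumes(model: DissectedAortaModel) -> dict[str, float]:
    """TL and FL volumes [mm^3] as signed-volume integrals over closed meshes.

    Raises ``GenerationError`` if a region boundary fails the watertightness
    check.
    """
    tl = model.tl_mesh()
    if not tl.is_watertight:
        raise GenerationError("TL region boundary is not watertight")
    out = {"TL": float(abs(tl.volume))}
    if model.flap is None:
        out["FL"] = 0.0
        return out
    fl = model.fl_mesh()
    if len(fl.faces) and not fl.is_watertight:
        raise GenerationError("FL region boundary is not watertight")
    out["FL"] = float(abs(fl.volume)) if len(fl.faces) else 0.0
    return out


def largest_inscribed_sphere_diameter(model: DissectedAortaModel,
                                      centerline: Centerline | None = None) -> float:
    """Diameter of the smallest inscribed sphere along the TL centerline [mm].

    For each centerline point, the distance to the nearest TL boundary is
    evaluated in its cross-section plane; the minimum over points, doubled,
    is the crimp target diameter of the deployment.
    """
    if centerline is None:
        centerline = model.tl_centerline
    stations = model.centerline.nearest_station(centerline.points)
    best = math.inf
    for p, i in zip(centerline.points, stations):
        poly = model._polygons[int(i)]["TL"]
        xy = model.to_frame(int(i), p[None, :])[0]
        pt = Point(xy[0], xy[1])
        if not poly.contains(pt):
            raise GenerationError("centerline point lies outside the true lumen")
        best = min(best, poly.exterior.distance(pt))
    return 2.0 * best
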