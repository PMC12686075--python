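"""Parametric bare-metal stent: sinusoidal wire rings wrapped to a cylinder.

The device modelled is a Zenith-style self-expanding Z-stent: independent
nitinol support rings, each a sinusoid drawn in the flat plane and wrapped
onto the design cylinder, joined to their neighbours by sutures that carry
tension but essentially no compression. The default design is 185 mm long
with 9 support rings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .materials import NITINOL, LinearElasticParams

__all__ = ["StentDesign", "WireMesh", "SutureSet", "generate_ring_curve",
           "wrap_to_cylinder", "build_stent", "DEFAULT_DESIGN"]


@dataclass(frozen=True)
class StentDesign:
    """Geometric description of the ring stent (lengths in mm).

    The axial layout must be consistent:
    ``total_length = n_rings * 2 * ring_amplitude + (n_rings - 1) * inter_ring_gap``.
    ``ring_amplitude`` is solved from the other defaults when left ``None``.
    The wire radius default is the value calibrated so the crimping radial
    force at 30 mm diameter reproduces the 1.7 N/mm bench anchor for this
    device class (see the deployment module).
    """

    total_length: float = 185.0
    n_rings: int = 9
    nominal_diameter: float = 36.0
    peaks_per_ring: int = 9
    ring_amplitude: float | None = None
    inter_ring_gap: float = 4.0
    wire_radius: float = 0.4554
    elements_per_ring: int = 72
    material: LinearElasticParams = field(default=NITINOL)

    def __post_init__(self) -> None:
        if self.n_rings < 1:
            raise ValueError("n_rings must be >= 1")
        if not self.wire_radius > 0:
            raise ValueError("wire_radius must be positive")
        if self.peaks_per_ring < 2:
            raise ValueError("peaks_per_ring must be >= 2")
        if self.ring_amplitude is None:
            amp = (self.total_length - (self.n_rings - 1) * self.inter_ring_gap) \
                / (2.0 * self.n_rings)
            if amp <= 0:
                raise ValueError("inconsistent total_length / gap: amplitude <= 0")
            object.__setattr__(self, "ring_amplitude", amp)
        expect = self.n_rings * 2 * self.ring_amplitude \
            + (self.n_rings - 1) * self.inter_ring_gap
        if abs(expect - self.total_length) > 1e-6:
            raise ValueError(
                f"axial layout inconsistent: rings+gaps span {expect} mm, "
                f"total_length is {self.total_length} mm")
        if self.n_rings > 1 and self.inter_ring_gap < 0:
            raise ValueError("overlapping rings: inter_ring_gap < 0")

    def with_resolution(self, elements_per_ring: int) -> "StentDesign":
        return replace(self, elements_per_ring=elements_per_ring)

    @property
    def wire_area(self) -> float:
        """Cross-section area pi r^2 [mm^2]."""
        return float(np.pi * self.wire_radius ** 2)

    @property
    def wire_bending_inertia(self) -> float:
        """Second moment pi r^4 / 4 [mm^4] of the circular wire section."""
        return float(np.pi * self.wire_radius ** 4 / 4.0)

    def ring_center_z(self, ring_index: int) -> float:
        a, g = self.ring_amplitude, self.inter_ring_gap
        return a + ring_index * (2 * a + g)


DEFAULT_DESIGN = StentDesign()


@dataclass
class WireMesh:
    """Beam-element wire mesh: nodes (n, 3) [mm], elements as node pairs."""

    nodes: np.ndarray
    elements: np.ndarray          # (m, 2) int
    ring_id: np.ndarray           # (m,) int per element
    node_ring_id: np.ndarray      # (n,) int per node
    design: StentDesign

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def axial_extent(self) -> float:
        """Max minus min coordinate along the stent axis (z at build time)."""
        return float(self.nodes[:, 2].max() - self.nodes[:, 2].min())

    def ring_loops(self) -> list[np.ndarray]:
        """Ordered node indices of each closed ring loop."""
        return [np.where(self.node_ring_id == r)[0]
                for r in range(self.design.n_rings)]

    def element_lengths(self) -> np.ndarray:
        d = self.nodes[self.elements[:, 1]] - self.nodes[self.elements[:, 0]]
        return np.linalg.norm(d, axis=1)


@dataclass
class SutureSet:
    """Tension-only spring links joining peaks of adjacent rings."""

    links: np.ndarray             # (k, 2) node indices
    rest_length: np.ndarray       # (k,)
    tensile_stiffness: float      # N/mm
    compressive_stiffness: float = 0.0

    def __post_init__(self) -> None:
        if self.tensile_stiffness <= 0:
            raise ValueError("tensile stiffness must be positive")
        if self.compressive_stiffness > 1e-6 * self.tensile_stiffness:
            raise ValueError("suture links must be quasi tension-only")

    def force(self, extension: np.ndarray) -> np.ndarray:
        """Axial spring force for a given extension (positive = stretched)."""
        ext = np.asarray(extension, dtype=float)
        return np.where(ext > 0, self.tensile_stiffness * ext,
                        self.compressive_stiffness * ext)


def generate_ring_curve(design: StentDesign, ring_index: int) -> np.ndarray:
    """One support ring drawn flat: points (x, z) with z = z_c + a sin(p s).

    x covers one circumference [0, pi*D); s = 2 x / D is the unwrapped
    angular coordinate. Returns an (elements_per_ring, 2) closed polyline
    (closure is implicit, the last point does not repeat the first).
    """
    if not 0 <= ring_index < design.n_rings:
        raise ValueError("ring_index out of range")
    n = design.elements_per_ring
    if n < 4 * design.peaks_per_ring:
        raise ValueError("elements_per_ring must be >= 4 * peaks_per_ring to "
                         "resolve the sinusoid")
    s = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x = s * design.nominal_diameter / 2.0
    z = design.ring_center_z(ring_index) \
        + design.ring_amplitude * np.sin(design.peaks_per_ring * s)
    return np.stack([x, z], axis=1)


def wrap_to_cylinder(planar_rings: list[np.ndarray], diameter: float) -> "WireMesh":
    """Wrap flat ring polylines onto the cylinder of the given diameter.

    (x, z) -> (r cos theta, r sin theta, z) with theta = 2 x / diameter; the
    planar x-extent must equal the circumference pi * diameter (one full wrap).
    """
    r = diameter / 2.0
    nodes, elements, ring_id, node_ring = [], [], [], []
    offset = 0
    for k, ring in enumerate(planar_rings):
        ring = np.asarray(ring, dtype=float)
        n = len(ring)
        dx = ring[1, 0] - ring[0, 0]
        extent = ring[:, 0].max() - ring[:, 0].min() + dx
        if abs(extent - np.pi * diameter) > 1e-6 * np.pi * diameter:
            raise ValueError("planar x-extent does not match the cylinder "
                             f"circumference: {extent} vs {np.pi * diameter}")
        theta = 2.0 * ring[:, 0] / diameter
        nodes.append(np.stack([r * np.cos(theta), r * np.sin(theta), ring[:, 1]], axis=1))
        idx = offset + np.arange(n)
        elements.append(np.stack([idx, offset + (np.arange(n) + 1) % n], axis=1))
        ring_id.append(np.full(n, k))
        node_ring.append(np.full(n, k))
        offset += n
    design = None
    mesh = WireMesh(np.concatenate(nodes), np.concatenate(elements),
                    np.concatenate(ring_id), np.concatenate(node_ring),
                    design)
    return mesh


def _peak_nodes(design: StentDesign, kind: str) -> np.ndarray:
    """Sample indices of the sinusoid maxima ('top') or minima ('bottom')."""
    n, p = design.elements_per_ring, design.peaks_per_ring
    s = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    target = (np.pi / 2 if kind == "top" else 3 * np.pi / 2)
    peaks_s = (target + 2.0 * np.pi * np.arange(p)) / p
    return np.argmin(np.abs(s[None, :] - peaks_s[:, None]) % (2 * np.pi), axis=1)


def build_stent(design: StentDesign,
                suture_stiffness: float = 5.0) -> tuple[WireMesh, SutureSet]:
    """Assemble the full wire mesh and the suture links.

    Each ring's top peaks are linked to the circumferentially nearest bottom
    peaks of the next ring. Suture tensile stiffness defaults to 5 N/mm,
    a soft polymer-thread scale; compression stiffness is zero.
    """
    rings = [generate_ring_curve(design, k) for k in range(design.n_rings)]
    mesh = wrap_to_cylinder(rings, design.nominal_diameter)
    mesh.design = design

    n = design.elements_per_ring
    top = _peak_nodes(design, "top")
    bottom = _peak_nodes(design, "bottom")
    links = []
    for k in range(design.n_rings - 1):
        for t in top:
            j = bottom[np.argmin(np.abs((bottom - t + n // 2) % n - n // 2))]
            links.append([k * n + t, (k + 1) * n + j])
    links = np.asarray(links, dtype=int) if links else np.empty((0, 2), int)
    rest = np.linalg.norm(mesh.nodes[links[:, 1]] - mesh.nodes[links[:, 0]], axis=1) \
        if len(links) else np.empty(0)
    sutures = SutureSet(links, rest, tensile_stiffness=suture_stiffness)
    return mesh, sutures
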