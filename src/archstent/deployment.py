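"""Three-phase virtual stent deployment and radial-force extraction.

Phases
------
1. **Radial crimp** — a kinematic cylindrical crimper (prescribed radius,
   no elasticity of its own) contracts around the free stent until the
   outer diameter matches the crimp target (the largest inscribed sphere of
   the true lumen). The proximal ring is held axially, mimicking
   intra-operative handling.
2. **Centerline alignment** — the crimper, and the stent riding inside it,
   is bent onto the true-lumen centerline by the point-by-point schedule of
   :mod:`archstent.alignment`; every cross-section moves rigidly, so the
   crimped stent is transported without additional deformation.
3. **Release / self-expansion** — the crimper radius is grown step by step;
   the stent expands driven by its stored elastic energy, contacts switch
   from stent–crimper to stent–wall once the crimper clears the lumen, and
   the dissection flap (an elastic shell with stiffness scaled by the
   flap-to-wall ratio) deflects under stent contact.

Radial force is extracted from the crimp phase by the paired-simulation
subtraction: reactions with the stent present minus reactions of the empty
crimper, normalised by stent length.

Units: mm, N, MPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import compute_alignment_schedule
from .anatomy import DissectedAortaModel, largest_inscribed_sphere_diameter, lumen_volumes
from .geometry import Centerline
from .materials import HyperelasticParams, small_strain_modulus
from .solver import SolverError, StructuralModel
from .stent import StentDesign, SutureSet, WireMesh, build_stent

__all__ = [
    "ContactParams", "Crimper", "DeploymentState", "RadialForceProfile",
    "build_crimper", "crimp_radial", "radial_force_profile",
    "release_and_expand", "beam_von_mises", "deploy_in_anatomy",
]


@dataclass(frozen=True)
class ContactParams:
    """Contact settings shared by all four pairs.

    ``penalty_stiffness = None`` resolves to 100x the local wire bending
    stiffness 3 EI / l^3. Friction is Coulomb with elastic-slip (stick
    displacements penalised, force capped at mu * |Fn|).
    """

    friction: float = 0.1
    penalty_stiffness: float | None = None
    stent_crimper: bool = True
    stent_wall: bool = True
    flap_wall: bool = True
    stent_flap: bool = True

    def __post_init__(self) -> None:
        if self.friction < 0:
            raise ValueError("friction must be non-negative")

    def resolve_penalty(self, design: StentDesign, seg_len: float) -> float:
        if self.penalty_stiffness is not None:
            return self.penalty_stiffness
        EI = design.material.E_MPa * design.wire_bending_inertia
        return 100.0 * 3.0 * EI / seg_len ** 3


@dataclass
class Crimper:
    """Kinematic tubular shell: a node grid on a cylinder with a radius
    schedule. Default grid reproduces 2,350 quadrilateral facets."""

    length: float
    radius: float
    n_axial: int = 48
    n_circ: int = 50
    z0: float = 0.0

    @property
    def facet_count(self) -> int:
        return (self.n_axial - 1) * self.n_circ

    def node_grid(self, radius: float | None = None) -> np.ndarray:
        r = self.radius if radius is None else radius
        z = np.linspace(self.z0, self.z0 + self.length, self.n_axial)
        th = np.linspace(0, 2 * np.pi, self.n_circ, endpoint=False)
        Z, TH = np.meshgrid(z, th, indexing="ij")
        return np.stack([r * np.cos(TH), r * np.sin(TH), Z], axis=-1).reshape(-1, 3)

    def centerline(self, n: int | None = None) -> Centerline:
        n = self.n_axial if n is None else n
        z = np.linspace(self.z0, self.z0 + self.length, n)
        pts = np.stack([np.zeros(n), np.zeros(n), z], axis=1)
        tan = np.tile([0.0, 0.0, 1.0], (n, 1))
        return Centerline(pts, tan)


def build_crimper(design: StentDesign, margin: float = 5.0,
                  clearance: float = 0.5) -> Crimper:
    """Crimper enclosing the free stent with a small radial clearance."""
    return Crimper(length=design.total_length + 2 * margin,
                   radius=design.nominal_diameter / 2 + clearance,
                   z0=-margin)


@dataclass
class RadialForceProfile:
    """Radial force per unit stent length vs stent outer diameter."""

    diameters: np.ndarray        # mm
    force_per_length: np.ndarray  # N/mm

    def at(self, diameter: float) -> float:
        order = np.argsort(self.diameters)
        return float(np.interp(diameter, self.diameters[order],
                               self.force_per_length[order]))

    def to_csv(self, path) -> None:
        np.savetxt(path, np.stack([self.diameters, self.force_per_length], axis=1),
                   delimiter=",", header="diameter_mm,force_N_per_mm", comments="")


@dataclass
class DeploymentState:
    """Snapshot of the stent (and optionally flap) after a deployment phase."""

    mesh: WireMesh
    nodes: np.ndarray
    phase: str                           # crimped | aligned | expanded
    element_strain: np.ndarray
    element_curvature: np.ndarray        # 1/mm, bending curvature change
    residual: float
    converged: bool
    crimper_radius: float
    elastic_energy: float
    reaction_radial: float = 0.0         # total radial crimper reaction [N]
    flap_grid: np.ndarray | None = None  # deformed flap mid-surface (full res)
    aorta: DissectedAortaModel | None = None
    tl_min_diameter: float | None = None
    fl_volume: float | None = None
    flap_displacement_max: float | None = None
    log: list = field(default_factory=list)

    @property
    def von_mises(self) -> np.ndarray:
        return beam_von_mises(self)


def beam_von_mises(state: DeploymentState) -> np.ndarray:
    """Outer-fiber equivalent stress per beam element [MPa].

    sigma = E * (|eps_axial| + |kappa| * r_wire): uniaxial fiber stress from
    membrane strain plus bending curvature change; torsion neglected.
    """
    design = state.mesh.design
    E = design.material.E_MPa
    return E * (np.abs(state.element_strain)
                + np.abs(state.element_curvature) * design.wire_radius)


# --------------------------------------------------------------------------
# structural assembly helpers
# --------------------------------------------------------------------------

def _turning_angles(X: np.ndarray, triples: np.ndarray) -> np.ndarray:
    a, b, c = triples.T
    t1 = X[b] - X[a]
    t2 = X[c] - X[b]
    t1 = t1 / np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = t2 / np.linalg.norm(t2, axis=1, keepdims=True)
    return np.arccos(np.clip(np.einsum("ij,ij->i", t1, t2), -1, 1))


def _wire_model(mesh: WireMesh, sutures: SutureSet | None) -> tuple[StructuralModel, dict]:
    """Structural model of the stent wire: axial + bending + suture links."""
    design = mesh.design
    E = design.material.E_MPa
    EA = E * design.wire_area
    EI = E * design.wire_bending_inertia
    model = StructuralModel(mesh.nodes)
    elements = mesh.elements
    L0 = mesh.element_lengths()
    model.add_axial_springs(elements, EA / L0, L0)
    n_ring = design.elements_per_ring
    triples = []
    for k in range(design.n_rings):
        idx = k * n_ring + np.arange(n_ring)
        triples.append(np.stack([idx[np.arange(-1, n_ring - 1)], idx,
                                 idx[(np.arange(n_ring) + 1) % n_ring]], axis=1))
    triples = np.concatenate(triples)
    # per-hinge arc length: mean of the two adjacent rest segment lengths
    lbar = np.empty(len(triples))
    for k in range(design.n_rings):
        sl = slice(k * n_ring, (k + 1) * n_ring)
        Lr = L0[sl]
        lbar[sl] = 0.5 * (np.roll(Lr, 1) + Lr)
    theta0 = _turning_angles(mesh.nodes, triples)
    model.add_bending(triples, EI / lbar, theta0)
    if sutures is not None and len(sutures.links):
        model.add_tension_links(sutures.links, sutures.tensile_stiffness,
                                sutures.rest_length, sutures.compressive_stiffness)
    meta = {"triples": triples, "L0": L0, "lbar": float(L0.mean()),
            "lbar_hinge": lbar, "n_stent": mesh.n_nodes, "EA": EA, "EI": EI}
    return model, meta


def _element_measures(model: StructuralModel, mesh: WireMesh,
                      meta: dict) -> tuple[np.ndarray, np.ndarray]:
    """Per-element axial strain and bending curvature change of the wire."""
    X = model.X[:meta["n_stent"]]
    d = X[mesh.elements[:, 1]] - X[mesh.elements[:, 0]]
    L = np.linalg.norm(d, axis=1)
    strain = (L - meta["L0"]) / meta["L0"]
    dev = model.bending_deviation()[:len(meta["triples"])]
    kappa_node = np.abs(dev) / meta["lbar_hinge"]
    # element curvature = mean of its two end-node hinge curvatures
    n_ring = mesh.design.elements_per_ring
    kappa_el = np.empty(len(mesh.elements))
    for k in range(mesh.design.n_rings):
        sl = slice(k * n_ring, (k + 1) * n_ring)
        kn = kappa_node[sl]
        kappa_el[sl] = 0.5 * (kn + np.roll(kn, -1))
    return strain, kappa_el


class _HuberFriction:
    """Elastic-slip Coulomb friction: stick displacement penalised with
    stiffness k_t, force capped at mu * |Fn| (Huber-smoothed energy).
    Anchors and normal-force caps are frozen at each macro step."""

    def __init__(self, k_t: float, mu: float):
        self.k_t = k_t
        self.mu = mu
        self.anchors: np.ndarray | None = None
        self.caps: np.ndarray | None = None
        self.normals: np.ndarray | None = None

    def reset(self, X: np.ndarray, normal_force: np.ndarray,
              normal_dir: np.ndarray) -> None:
        """Freeze anchors, force caps and normals at a macro-step start so the
        friction energy has an exactly consistent gradient within the step."""
        self.anchors = X.copy()
        self.caps = self.mu * np.abs(normal_force)
        self.normals = normal_dir.copy()

    def energy_force(self, X: np.ndarray) -> tuple[float, np.ndarray]:
        if self.anchors is None or self.mu <= 0:
            return 0.0, np.zeros_like(X)
        d = X - self.anchors
        d_t = d - np.einsum("ij,ij->i", d, self.normals)[:, None] * self.normals
        nt = np.linalg.norm(d_t, axis=1)
        cap = self.caps
        elastic = self.k_t * nt <= cap
        E = np.where(elastic, 0.5 * self.k_t * nt ** 2,
                     cap * nt - cap ** 2 / (2 * self.k_t))
        F = np.where(elastic[:, None], -self.k_t * d_t,
                     -cap[:, None] * d_t / np.maximum(nt, 1e-12)[:, None])
        return float(E.sum()), F


class _CrimperContact:
    """Radial cap around a (possibly curved) axis for a subset of nodes."""

    def __init__(self, node_idx: np.ndarray, centers: np.ndarray,
                 tangents: np.ndarray, kp: float, mu: float, r_wire: float):
        self.idx = node_idx
        self.P = centers
        self.T = tangents
        self.kp = kp
        self.r_wire = r_wire
        self.r_cap = np.inf
        self.active = True
        self.friction = _HuberFriction(kp / 10.0, mu)
        self.last_reaction = 0.0

    def _geometry(self, X: np.ndarray):
        rel = X[self.idx] - self.P
        ax = np.einsum("ij,ij->i", rel, self.T)
        rad = rel - ax[:, None] * self.T
        rho = np.linalg.norm(rad, axis=1)
        rhat = rad / np.maximum(rho, 1e-12)[:, None]
        return rho, rhat

    # the cap radius bounds the wire-centerline (node) circle; stent
    # diameters are therefore node-circle diameters throughout
    def penetration(self, X: np.ndarray) -> np.ndarray:
        rho, _ = self._geometry(X)
        return np.maximum(rho - self.r_cap, 0.0)

    def reset_friction(self, X: np.ndarray) -> None:
        rho, rhat = self._geometry(X)
        pen = np.maximum(rho - self.r_cap, 0.0)
        self.friction.reset(X[self.idx], self.kp * pen, rhat)

    def __call__(self, X: np.ndarray) -> tuple[float, np.ndarray]:
        F = np.zeros_like(X)
        if not self.active or not math.isfinite(self.r_cap):
            return 0.0, F
        rho, rhat = self._geometry(X)
        pen = np.maximum(rho - self.r_cap, 0.0)
        E = float(0.5 * self.kp * np.sum(pen ** 2))
        Fn = -(self.kp * pen)[:, None] * rhat
        self.last_reaction = float(self.kp * pen.sum())
        Ef, Ft = self.friction.energy_force(X[self.idx])
        np.add.at(F, self.idx, Fn + Ft)
        return E + Ef, F


class _WallContact:
    """Keeps stent nodes inside the (rigid) wall circle of their station."""

    def __init__(self, node_idx, aorta: DissectedAortaModel, kp, mu, r_wire):
        self.idx = node_idx
        self.aorta = aorta
        self.kp = kp
        self.mu = mu
        self.r_wire = r_wire
        self.friction = _HuberFriction(kp / 10.0, mu)
        self.station = None
        self.active = True

    def assign_stations(self, X: np.ndarray) -> None:
        self.station = self.aorta.centerline.nearest_station(X[self.idx])
        self.C = self.aorta.centerline.points[self.station]
        self.E1 = self.aorta.e1[self.station]
        self.E2 = self.aorta.e2[self.station]
        self.Rw = self.aorta.wall_radius[self.station]

    def _geometry(self, X: np.ndarray):
        rel = X[self.idx] - self.C
        x = np.einsum("ij,ij->i", rel, self.E1)
        y = np.einsum("ij,ij->i", rel, self.E2)
        rho = np.hypot(x, y)
        rhat = (x / np.maximum(rho, 1e-12))[:, None] * self.E1 \
            + (y / np.maximum(rho, 1e-12))[:, None] * self.E2
        return rho, rhat

    def reset_friction(self, X: np.ndarray) -> None:
        rho, rhat = self._geometry(X)
        pen = np.maximum(rho - (self.Rw - self.r_wire), 0.0)
        self.friction.reset(X[self.idx], self.kp * pen, rhat)

    def __call__(self, X: np.ndarray) -> tuple[float, np.ndarray]:
        F = np.zeros_like(X)
        if not self.active:
            return 0.0, F
        rho, rhat = self._geometry(X)
        pen = np.maximum(rho - (self.Rw - self.r_wire), 0.0)
        E = float(0.5 * self.kp * np.sum(pen ** 2))
        Fn = -(self.kp * pen)[:, None] * rhat
        Ef, Ft = self.friction.energy_force(X[self.idx])
        np.add.at(F, self.idx, Fn + Ft)
        return E + Ef, F


class _FlapStentContact:
    """Cross-section contact between stent nodes and the flap polyline.

    Flap nodes move along their station's e1 axis only, so each flap row is
    a fixed-abscissa graph x(y); a stent node at in-plane (x, y) with
    x < x_flap(y) + t/2 + r_wire is penalised, the reaction being shared
    between the two bracketing flap nodes.
    """

    def __init__(self, stent_idx, aorta, flap_rows_nodes, flap_rows_y,
                 row_of_station, kp, t_half, r_wire):
        self.idx = stent_idx
        self.aorta = aorta
        self.rows_nodes = flap_rows_nodes    # list of node-id arrays per row
        self.rows_y = flap_rows_y            # list of fixed y arrays per row
        self.row_of_station = row_of_station  # dict station -> row index
        self.kp = kp
        self.offset = t_half + r_wire
        self.active = True
        self.pairs = None                    # computed by assign

    def assign(self, X: np.ndarray) -> None:
        """Freeze stent-node -> flap-segment bracketing for a macro step."""
        st = self.aorta.centerline.nearest_station(X[self.idx])
        items = []
        for n_local, j in enumerate(st):
            row = self.row_of_station.get(int(j))
            if row is None:
                continue
            yrow = self.rows_y[row]
            if yrow[0] - yrow[-1] < 1e-6:
                continue          # pinched row
            rel = X[self.idx[n_local]] - self.aorta.centerline.points[j]
            # rows run from A (+y) to B (-y): descending y; clamping extends
            # the barrier to the wall attachments so nodes cannot wrap around
            # the flap edge into the false lumen
            y = float(np.clip(rel @ self.aorta.e2[j],
                              yrow[-1] + 1e-9, yrow[0] - 1e-9))
            seg = int(np.searchsorted(-yrow, -y) - 1)
            seg = min(max(seg, 0), len(yrow) - 2)
            w2 = (yrow[seg] - y) / (yrow[seg] - yrow[seg + 1])
            items.append((n_local, j, self.rows_nodes[row][seg],
                          self.rows_nodes[row][seg + 1], 1.0 - w2, w2))
        if items:
            arr = np.array(items, dtype=float)
            self.pairs = {
                "local": arr[:, 0].astype(int), "station": arr[:, 1].astype(int),
                "f1": arr[:, 2].astype(int), "f2": arr[:, 3].astype(int),
                "w1": arr[:, 4], "w2": arr[:, 5]}
        else:
            self.pairs = None

    def __call__(self, X: np.ndarray) -> tuple[float, np.ndarray]:
        F = np.zeros_like(X)
        if not self.active or self.pairs is None:
            return 0.0, F
        p = self.pairs
        j = p["station"]
        e1 = self.aorta.e1[j]
        C = self.aorta.centerline.points[j]
        sx = np.einsum("ij,ij->i", X[self.idx[p["local"]]] - C, e1)
        xf = p["w1"] * np.einsum("ij,ij->i", X[p["f1"]] - C, e1) \
            + p["w2"] * np.einsum("ij,ij->i", X[p["f2"]] - C, e1)
        pen = np.maximum(xf + self.offset - sx, 0.0)
        E = float(0.5 * self.kp * np.sum(pen ** 2))
        f = self.kp * pen
        np.add.at(F, self.idx[p["local"]], f[:, None] * e1)
        np.add.at(F, p["f1"], -(f * p["w1"])[:, None] * e1)
        np.add.at(F, p["f2"], -(f * p["w2"])[:, None] * e1)
        return E, F


class _FlapWallContact:
    """Keeps flap nodes inside the wall circle (radius Rw - t/2)."""

    def __init__(self, node_idx, e1_dirs, x0, y_fixed, limit, kp):
        self.idx = node_idx
        self.e1 = e1_dirs
        self.x0 = x0            # reference points (station centers)
        self.y = y_fixed
        self.limit = limit      # per node: max |x| given fixed y
        self.kp = kp
        self.active = True

    def __call__(self, X: np.ndarray) -> tuple[float, np.ndarray]:
        F = np.zeros_like(X)
        if not self.active:
            return 0.0, F
        x = np.einsum("ij,ij->i", X[self.idx] - self.x0, self.e1)
        pen_lo = np.maximum(-self.limit - x, 0.0)
        pen_hi = np.maximum(x - self.limit, 0.0)
        E = float(0.5 * self.kp * np.sum(pen_lo ** 2 + pen_hi ** 2))
        f = self.kp * (pen_lo - pen_hi)
        np.add.at(F, self.idx, f[:, None] * self.e1)
        return E, F


class _TangentHold:
    """Weak springs along the local tangent: a regularisation standing in for
    the axial grip of friction, removing rigid sliding modes."""

    def __init__(self, node_idx, tangents, X_ref, k=0.05):
        self.idx = node_idx
        self.T = tangents
        self.ref = X_ref.copy()
        self.k = k

    def __call__(self, X: np.ndarray) -> tuple[float, np.ndarray]:
        d = np.einsum("ij,ij->i", X[self.idx] - self.ref, self.T)
        E = float(0.5 * self.k * np.sum(d ** 2))
        F = np.zeros_like(X)
        np.add.at(F, self.idx, -(self.k * d)[:, None] * self.T)
        return E, F


# --------------------------------------------------------------------------
# phase 1: radial crimp (+ radial force)
# --------------------------------------------------------------------------

def _proximal_extrema(design: StentDesign) -> np.ndarray:
    """Node indices of the proximal (lowest-z) extrema of the first ring."""
    n, p = design.elements_per_ring, design.peaks_per_ring
    s = np.linspace(0, 2 * np.pi, n, endpoint=False)
    z = np.sin(p * s)
    return np.where(np.isclose(z, z.min()))[0]


def crimp_radial(mesh: WireMesh, crimper: Crimper | None = None,
                 target_diameter: float | None = None,
                 sutures: SutureSet | None = None,
                 contacts: ContactParams = ContactParams(),
                 n_steps: int = 16, max_iter: int = 6000, tol_rel: float = 2e-3,
                 record_diameters: np.ndarray | None = None,
                 ) -> tuple[DeploymentState, np.ndarray]:
    """Quasi-statically crimp the stent to ``target_diameter`` (outer).

    Returns the crimped state and a record array of (outer diameter [mm],
    total radial crimper reaction [N]) at every accepted macro step.
    """
    design = mesh.design
    if crimper is None:
        crimper = build_crimper(design)
    if target_diameter is None:
        raise ValueError("target_diameter is required")
    if target_diameter > design.nominal_diameter:
        raise ValueError("crimp target exceeds the stent nominal diameter")

    model, meta = _wire_model(mesh, sutures)
    kp = contacts.resolve_penalty(design, meta["lbar"])
    n = mesh.n_nodes
    centers = np.zeros((n, 3))
    centers[:, 2] = mesh.nodes[:, 2]
    tangents = np.tile([0.0, 0.0, 1.0], (n, 1))
    contact = _CrimperContact(np.arange(n), centers, tangents, kp,
                              contacts.friction if contacts.stent_crimper else 0.0,
                              design.wire_radius)
    contact.active = contacts.stent_crimper
    model.add_contact(contact)
    # hold each ring's mean axial position (rigid-mode regularisation only)
    ring_mean_refs = [float(mesh.nodes[mesh.node_ring_id == k, 2].mean())
                      for k in range(design.n_rings)]

    def ring_hold(X: np.ndarray) -> tuple[float, np.ndarray]:
        F = np.zeros_like(X)
        E = 0.0
        K = 1.0
        for k in range(design.n_rings):
            sel = mesh.node_ring_id == k
            dz = float(X[sel, 2].mean()) - ring_mean_refs[k]
            E += 0.5 * K * dz * dz
            F[sel, 2] -= K * dz / sel.sum()
        return E, F

    model.add_contact(ring_hold)
    model.constrain_to_plane(_proximal_extrema(design), np.array([0.0, 0.0, 1.0]))
    model.precond_extra[:] = kp

    r_start = design.nominal_diameter / 2 + 0.25
    r_end = target_diameter / 2
    radii = np.linspace(r_start, r_end, n_steps + 1)[1:]
    if record_diameters is not None:
        extra = np.asarray(record_diameters, float) / 2
        radii = np.unique(np.concatenate([radii, extra]))[::-1]
        radii = radii[radii >= r_end - 1e-12]
    record = []
    log = []
    res = None
    record_set = set(np.round(record_diameters, 6)) if record_diameters is not None \
        else None
    for r_cap in radii:
        contact.r_cap = float(r_cap)
        contact.reset_friction(model.X)
        res = model.relax(max_iter=max_iter, tol_rel=tol_rel, raise_on_fail=False)
        if res.f_char > 1e-9 and (record_set is None
                                  or float(np.round(2 * r_cap, 6)) in record_set
                                  or r_cap == radii[-1]):
            # friction-neutral hold: refresh the stick anchors at this radius
            # and re-equilibrate, so the recorded reaction does not carry the
            # tangential stick history of the loading schedule
            contact.reset_friction(model.X)
            res = model.relax(max_iter=max_iter, tol_rel=tol_rel,
                              raise_on_fail=False)
            model.evaluate(model.X)     # refresh contact reaction bookkeeping
        model.update_bend_references()
        outer = 2 * np.linalg.norm(model.X[:, :2], axis=1).max()
        record.append((outer, contact.last_reaction))
        log.append({"r_cap": float(r_cap), "outer_diameter": outer,
                    "residual": res.residual, "iterations": res.iterations,
                    "reaction_N": contact.last_reaction})
    if res is not None and not res.converged and res.residual > 10 * tol_rel * res.f_char:
        raise SolverError(f"crimp failed to converge: residual {res.residual:.3e}")
    strain, kappa = _element_measures(model, mesh, meta)
    state = DeploymentState(
        mesh=mesh, nodes=model.X.copy(), phase="crimped",
        element_strain=strain, element_curvature=kappa,
        residual=res.residual, converged=res.converged,
        crimper_radius=float(radii[-1]), elastic_energy=model.elastic_energy(),
        reaction_radial=contact.last_reaction, log=log)
    return state, np.array(record)


def radial_force_profile(design_or_mesh, diameter_grid,
                         sutures: SutureSet | None = None,
                         contacts: ContactParams = ContactParams(),
                         **crimp_kw) -> RadialForceProfile:
    """Radial force per unit length by paired crimp simulations.

    Simulation A crimps the stent inside the kinematic crimper down to the
    smallest requested diameter, recording the total radial reaction;
    simulation B drives the empty crimper through the same schedule (its
    reaction is identically zero for a kinematic tool). The profile is
    (A - B) / stent length, evaluated on the requested diameter grid;
    entries at or above the free diameter report zero force.
    """
    if isinstance(design_or_mesh, WireMesh):
        mesh = design_or_mesh
        design = mesh.design
        if sutures is None:
            raise ValueError("pass sutures together with a prebuilt mesh")
    else:
        design = design_or_mesh
        mesh, sutures = build_stent(design)
    grid = np.sort(np.asarray(diameter_grid, float))
    if np.any(grid <= 0):
        raise ValueError("diameter grid must be positive")
    below = grid[grid < design.nominal_diameter]
    if len(below) == 0:
        return RadialForceProfile(grid, np.zeros_like(grid))
    state, record = crimp_radial(
        mesh, target_diameter=float(below.min()), sutures=sutures,
        contacts=contacts, record_diameters=below, **crimp_kw)
    # B-run: empty crimper, identical schedule
    crimper = build_crimper(design)
    reaction_b = _empty_crimper_reaction(crimper, record[:, 0])
    dia = record[:, 0]
    force = (record[:, 1] - reaction_b) / design.total_length
    order = np.argsort(dia)
    out = np.interp(grid, dia[order], force[order], left=np.nan, right=0.0)
    out[grid >= design.nominal_diameter] = 0.0
    out = np.where(np.isnan(out), np.interp(grid, dia[order], force[order]), out)
    return RadialForceProfile(grid, out)


def _empty_crimper_reaction(crimper: Crimper, diameters: np.ndarray) -> np.ndarray:
    """Reaction of the crimper alone: zero at every diameter, the crimper
    being a purely kinematic (prescribed-displacement) tool."""
    return np.zeros_like(np.asarray(diameters, float))


# --------------------------------------------------------------------------
# phases 2 + 3: alignment and self-expansion in the anatomy
# --------------------------------------------------------------------------

def _flap_solver_rows(aorta: DissectedAortaModel, subsample: int = 2):
    """Select flap rows carried by the solver (every ``subsample``-th row,
    endpoints always included)."""
    nf = len(aorta.flap.station_indices)
    rows = list(range(0, nf, subsample))
    if rows[-1] != nf - 1:
        rows.append(nf - 1)
    return np.asarray(rows, int)


def release_and_expand(state: DeploymentState, aorta: DissectedAortaModel,
                       flap_material: HyperelasticParams,
                       contacts: ContactParams = ContactParams(),
                       placement_offset: float = 14.0,
                       n_steps: int = 24, max_iter: int = 6000,
                       tol_rel: float = 2e-3, flap_subsample: int = 2,
                       ) -> DeploymentState:
    """Align the crimped stent on the TL centerline and let it self-expand.

    The crimper is first bent onto the true-lumen centerline (both stent and
    crimper cross-sections move rigidly), then its radius is grown step by
    step. While growing, the stent follows passively under its stored
    energy; once the crimper clears the largest lumen radius the
    stent–crimper pair is deactivated and the stent bears on wall and flap.
    The flap is an elastic shell with membrane/bending stiffness from the
    scaled small-strain modulus, its attached edges fixed to the wall,
    interior nodes deflecting along the local e1 (push) direction.
    """
    if state.phase != "crimped":
        raise ValueError("release_and_expand expects a crimped state")
    mesh = state.mesh
    design = mesh.design

    # ---- phase 2: kinematic alignment onto the TL centerline
    tl = aorta.tl_centerline
    margin = 5.0
    s0 = placement_offset - margin
    s1 = placement_offset + design.total_length + margin
    if s1 > tl.length:
        raise ValueError("stent placement exceeds the TL centerline length")
    n_cl = max(int(round((s1 - s0) / 5.0)) + 1, 8)
    s_samples = np.linspace(s0, s1, n_cl)
    C0 = Centerline(tl.point_at(s_samples), tl.tangent_at(s_samples))
    C0 = C0.resample(n_cl)
    ds = C0.length / (n_cl - 1)
    zc = -margin + np.arange(n_cl) * ds
    Cc = Centerline(np.stack([np.zeros(n_cl), np.zeros(n_cl), zc], axis=1),
                    np.tile([0.0, 0.0, 1.0], (n_cl, 1)))
    schedule = compute_alignment_schedule(Cc, C0)
    attach = np.clip(np.round((state.nodes[:, 2] + margin) / ds).astype(int),
                     0, n_cl - 1)
    X_aligned = schedule.transform_nodes(schedule.n_states - 1, state.nodes, attach)

    # ---- phase 3: build the coupled stent + flap model
    model, meta = _wire_model(mesh, None)
    model.X = X_aligned.copy()
    model.update_bend_references()
    n_stent = mesh.n_nodes
    kp = contacts.resolve_penalty(design, meta["lbar"])

    flap = aorta.flap
    has_flap = flap is not None
    if has_flap:
        rows = _flap_solver_rows(aorta, flap_subsample)
        st_idx = flap.station_indices[rows]
        grid = flap.grid[rows]                  # (nr, nu, 3)
        nr, nu, _ = grid.shape
        flap_ids = n_stent + np.arange(nr * nu).reshape(nr, nu)
        X_all = np.concatenate([model.X, grid.reshape(-1, 3)])
    else:
        X_all = model.X.copy()
    full = StructuralModel(X_all)
    # adopt the wire members
    full._ax_ij, full._ax_k, full._ax_L0 = model._ax_ij, model._ax_k, model._ax_L0
    full._bend_abc, full._bend_k = model._bend_abc, model._bend_k
    full._bend_psi0, full._bend_ref = model._bend_psi0, model._bend_ref
    full._bend_track = model._bend_track
    full.precond_extra = np.zeros(full.n)
    sut = build_stent(design)[1]
    full.add_tension_links(sut.links, sut.tensile_stiffness, sut.rest_length,
                           sut.compressive_stiffness)

    fs_contact = fw_contact = None
    if has_flap:
        E_f = small_strain_modulus(flap_material)       # MPa
        t_f = flap.thickness
        ds_row = float(np.mean(np.diff(aorta.centerline.arclength[st_idx])))
        # membrane springs (stretch along u and s, diagonal shear)
        pairs, ks, L0s = [], [], []

        def _add(i, j, width):
            L = float(np.linalg.norm(X_all[i] - X_all[j]))
            if L < 1e-9:
                return
            pairs.append((i, j))
            ks.append(E_f * t_f * width / L)
            L0s.append(L)

        for r in range(nr):
            for u in range(nu - 1):
                _add(flap_ids[r, u], flap_ids[r, u + 1], ds_row)
        for r in range(nr - 1):
            for u in range(nu):
                w = float(np.linalg.norm(X_all[flap_ids[r, u]]
                                         - X_all[flap_ids[r, min(u + 1, nu - 1)]])) or ds_row
                _add(flap_ids[r, u], flap_ids[r + 1, u], w)
            for u in range(nu - 1):
                _add(flap_ids[r, u], flap_ids[r + 1, u + 1], 0.25 * ds_row)
                _add(flap_ids[r, u + 1], flap_ids[r + 1, u], 0.25 * ds_row)
        full.add_axial_springs(np.array(pairs), np.array(ks), np.array(L0s))
        # bending across the chord and along the axis; the sign references are
        # fixed vectors (local axial tangent / e2) so a flap section flipping
        # through flat is penalised consistently
        EI_f = E_f * t_f ** 3 / 12.0
        tri, ktri, refs = [], [], []
        for r in range(nr):
            j = int(st_idx[r])
            tan_j = aorta.centerline.tangents[j]
            for u in range(1, nu - 1):
                tri.append((flap_ids[r, u - 1], flap_ids[r, u], flap_ids[r, u + 1]))
                L = float(np.linalg.norm(X_all[flap_ids[r, u + 1]]
                                         - X_all[flap_ids[r, u - 1]])) / 2
                ktri.append(EI_f * ds_row / max(L, 1e-6))
                refs.append(tan_j)
        for r in range(1, nr - 1):
            j = int(st_idx[r])
            for u in range(nu):
                tri.append((flap_ids[r - 1, u], flap_ids[r, u], flap_ids[r + 1, u]))
                ktri.append(EI_f * 2.0 / ds_row)   # width ~ chord spacing aggregate
                refs.append(aorta.e2[j])
        tri = np.array(tri)
        refs = np.array(refs)
        cross = np.cross(X_all[tri[:, 1]] - X_all[tri[:, 0]],
                         X_all[tri[:, 2]] - X_all[tri[:, 1]])
        nrm = np.linalg.norm(cross, axis=1)
        use = nrm > 1e-9
        refs[use] = cross[use] / nrm[use, None]   # match the as-built sign exactly
        full.add_bending(tri, np.array(ktri), _turning_angles(X_all, tri),
                         references=refs)

        # flap constraints: attached edges fixed, interior moves along e1 only.
        # Nodes whose fixed chord ordinate lies within half a thickness of the
        # wall circle belong to the attachment zone and are held with the wall.
        flap_rows_y = []
        for r in range(nr):
            j = int(st_idx[r])
            rel = grid[r] - aorta.centerline.points[j]
            flap_rows_y.append(rel @ aorta.e2[j])
        edge = np.zeros((nr, nu), bool)
        edge[0, :] = edge[-1, :] = True
        edge[:, 0] = edge[:, -1] = True
        for r in range(nr):
            Rw_r = aorta.wall_radius[int(st_idx[r])]
            edge[r] |= np.abs(flap_rows_y[r]) > Rw_r - 0.5 * t_f - 0.2
        full.fix_nodes(flap_ids[edge])
        interior_ids = flap_ids[~edge]
        e1_per = np.repeat(aorta.e1[st_idx], nu, axis=0).reshape(nr, nu, 3)[~edge]
        full.constrain_to_line(interior_ids, e1_per)

    # proximal boundary condition: first-ring proximal extrema move only in
    # the plane perpendicular to the local centerline tangent
    prox = _proximal_extrema(design)
    t_prox = tl.tangent_at(placement_offset)
    full.constrain_to_plane(prox, t_prox)

    # contacts
    crimp_contact = _CrimperContact(
        np.arange(n_stent), C0.points[attach], C0.tangents[attach], kp,
        contacts.friction if contacts.stent_crimper else 0.0, design.wire_radius)
    crimp_contact.r_cap = state.crimper_radius
    crimp_contact.active = contacts.stent_crimper
    full.add_contact(crimp_contact)

    wall_contact = _WallContact(np.arange(n_stent), aorta, kp,
                                contacts.friction, design.wire_radius)
    wall_contact.assign_stations(X_all)
    wall_contact.active = contacts.stent_wall
    full.add_contact(wall_contact)

    if has_flap:
        # any flap station maps to its nearest solver row
        row_of_station = {}
        for r_full, s_full_idx in enumerate(flap.station_indices):
            nearest = int(np.argmin(np.abs(rows - r_full)))
            row_of_station[int(s_full_idx)] = nearest
        flap_rows_nodes = [flap_ids[r] for r in range(nr)]
        fs_contact = _FlapStentContact(np.arange(n_stent), aorta,
                                       flap_rows_nodes, flap_rows_y,
                                       row_of_station, kp,
                                       0.5 * t_f, design.wire_radius)
        fs_contact.active = contacts.stent_flap
        full.add_contact(fs_contact)

        int_rows, int_cols = np.where(~edge)
        fw_idx = flap_ids[~edge]
        fw_stations = st_idx[int_rows]
        e1w = aorta.e1[fw_stations]
        y_fixed = np.array([flap_rows_y[r][u] for r, u in zip(int_rows, int_cols)])
        Rw_w = aorta.wall_radius[fw_stations]
        limit = np.sqrt(np.maximum((Rw_w - 0.5 * t_f) ** 2 - y_fixed ** 2, 1e-6))
        fw_contact = _FlapWallContact(fw_idx, e1w,
                                      aorta.centerline.points[fw_stations],
                                      y_fixed, limit, kp)
        fw_contact.active = contacts.flap_wall
        full.add_contact(fw_contact)

    hold = _TangentHold(np.arange(n_stent), C0.tangents[attach], X_all[:n_stent])
    full.add_contact(hold)
    # contact penalties dominate the stiffness of the nodes they act on;
    # fold them into the preconditioner
    full.precond_extra[:] = kp

    # ---- crimper release schedule
    r_max = float(aorta.wall_radius.max()) + design.wire_radius + 1.0
    radii = np.linspace(state.crimper_radius, r_max, n_steps + 1)[1:]
    log = []
    res = None
    energies = []
    for r_cap in radii:
        crimp_contact.r_cap = float(r_cap)
        if r_cap > float(aorta.wall_radius.max()) and crimp_contact.active:
            # crimper exceeds the lumen: stent-crimper pair deactivated
            crimp_contact.active = False
        wall_contact.assign_stations(full.X)
        wall_contact.reset_friction(full.X)
        crimp_contact.reset_friction(full.X)
        if fs_contact is not None:
            fs_contact.assign(full.X)
        res = full.relax(max_iter=max_iter, tol_rel=tol_rel, raise_on_fail=False)
        full.update_bend_references()
        energies.append(full.elastic_energy())
        log.append({"r_cap": float(r_cap), "residual": res.residual,
                    "iterations": res.iterations,
                    "crimper_active": crimp_contact.active,
                    "elastic_energy": energies[-1]})
    # final equilibrium with contacts frozen off the crimper
    crimp_contact.active = False
    wall_contact.active = contacts.stent_wall
    wall_contact.assign_stations(full.X)
    wall_contact.reset_friction(full.X)
    if fs_contact is not None:
        fs_contact.assign(full.X)
    res = full.relax(max_iter=2 * max_iter, tol_rel=tol_rel, raise_on_fail=False)
    if not res.converged and res.residual > 10 * tol_rel * res.f_char:
        raise SolverError(f"expansion failed to converge: residual {res.residual:.3e}")

    strain, kappa = _element_measures(full, mesh, meta)
    if has_flap:
        # ---- write the deformed flap back to the full-resolution anatomy grid
        new_grid = _flap_writeback(aorta, rows, flap_ids, full.X)
        deformed = aorta.with_flap_grid(new_grid)
        disp_max = float(np.linalg.norm(new_grid - flap.grid, axis=2).max())
        fl_volume = lumen_volumes(deformed)["FL"]
    else:
        new_grid = None
        deformed = aorta
        disp_max = 0.0
        fl_volume = 0.0
    # the narrowest-TL metric is taken over the treated (stented) extent
    tl_post = deformed.tl_centerline
    s_keep = (tl_post.arclength >= placement_offset) \
        & (tl_post.arclength <= placement_offset + design.total_length)
    tl_seg = Centerline(tl_post.points[s_keep], tl_post.tangents[s_keep])
    state_out = DeploymentState(
        mesh=mesh, nodes=full.X[:n_stent].copy(), phase="expanded",
        element_strain=strain, element_curvature=kappa,
        residual=res.residual, converged=res.converged,
        crimper_radius=float(radii[-1]),
        elastic_energy=full.elastic_energy(),
        flap_grid=new_grid, aorta=deformed,
        tl_min_diameter=largest_inscribed_sphere_diameter(deformed, tl_seg),
        fl_volume=fl_volume,
        flap_displacement_max=disp_max, log=log)
    return state_out


def _flap_writeback(aorta: DissectedAortaModel, rows: np.ndarray,
                    flap_ids: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Interpolate solver-row flap displacements onto the full flap grid."""
    flap = aorta.flap
    nf, nu, _ = flap.grid.shape
    st_idx = flap.station_indices
    s_full = aorta.centerline.arclength[st_idx]
    s_rows = s_full[rows]
    disp_rows = np.zeros((len(rows), nu))
    for r in range(len(rows)):
        j = int(st_idx[rows[r]])
        e1 = aorta.e1[j]
        disp_rows[r] = (X[flap_ids[r]] - flap.grid[rows[r]]) @ e1
    new_grid = flap.grid.copy()
    for u in range(nu):
        d = np.interp(s_full, s_rows, disp_rows[:, u])
        for k in range(3):
            new_grid[:, u, k] += d * aorta.e1[st_idx][:, k]
    # interpolated rows can overshoot the wall where the pinch taper changes
    # clearance rapidly; clamp every row inside the wall offset
    t2 = 0.5 * flap.thickness
    for r, j in enumerate(st_idx):
        j = int(j)
        C = aorta.centerline.points[j]
        x = (new_grid[r] - C) @ aorta.e1[j]
        y = (new_grid[r] - C) @ aorta.e2[j]
        Rw = aorta.wall_radius[j]
        blim = np.sqrt(np.maximum((Rw - t2) ** 2 - y ** 2, 0.0))
        near_wall = np.abs(y) > Rw - t2 - 1e-9
        x_cl = np.clip(x, -blim, blim)
        # attachment zone: keep inside the wall circle itself
        rr = np.hypot(x, y)
        scale = np.where(near_wall & (rr > Rw), Rw / np.maximum(rr, 1e-12), 1.0)
        x_new = np.where(near_wall, x * scale, x_cl)
        y_new = np.where(near_wall, y * scale, y)
        new_grid[r] = C + np.outer(x_new, aorta.e1[j]) + np.outer(y_new, aorta.e2[j]) \
            + np.outer((new_grid[r] - C) @ aorta.centerline.tangents[j],
                       aorta.centerline.tangents[j])
    return new_grid


def deploy_in_anatomy(aorta: DissectedAortaModel, design: StentDesign,
                      flap_material: HyperelasticParams,
                      contacts: ContactParams = ContactParams(),
                      crimp_margin: float = 0.0,
                      **expand_kw) -> DeploymentState:
    """Full pipeline for one configuration: crimp to the inscribed-sphere
    diameter of the TL, align, and self-expand against wall and flap."""
    mesh, sutures = build_stent(design)
    target = largest_inscribed_sphere_diameter(aorta) - crimp_margin
    crimped, _ = crimp_radial(mesh, target_diameter=target, sutures=sutures,
                              contacts=contacts)
    return release_and_expand(crimped, aorta, flap_material, contacts,
                              **expand_kw)
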