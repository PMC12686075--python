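"""Pulsatile lattice-Boltzmann hemodynamics (D3Q19, single-relaxation BGK).

The lumen (true + false lumen and branch vessels, flap excluded) is
voxelized on a uniform grid; blood is advanced by stream-collide steps with
half-way bounce-back at rigid walls, an equilibrium velocity inlet driven by
the cardiac inlet waveform and equilibrium pressure (density) outlets at the
descending aorta and the three arch branches. Simulations run a fixed
number of cardiac cycles (three by default) and the last cycle is the one
analysed downstream.

Unit mapping: the physical time step follows from the prescribed lattice
Mach scale ``u_lat_peak`` (dt = u_lat_peak * dx / v_peak); the lattice
viscosity follows from the relaxation time tau, so the effective fluid
viscosity is nu_eff = (tau - 1/2)/3 * dx^2 / dt. At coarse desk-scale grids
this exceeds the physical viscosity of blood, i.e. runs are Reynolds-scaled;
``lattice_info`` reports the effective Reynolds number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .anatomy import DissectedAortaModel
from .waveforms import WaveformSpec

__all__ = ["FluidProps", "LatticeConfig", "VoxelLattice", "FlowField",
           "voxelize", "run_pulsatile_lbm"]

# D3Q19 velocity set and weights
_C = np.array([
    [0, 0, 0],
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
    [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
    [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
    [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1]], dtype=np.int64)
_W = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12)
_OPP = np.array([0, 2, 1, 4, 3, 6, 5, 8, 7, 10, 9, 12, 11, 14, 13,
                 16, 15, 18, 17], dtype=np.int64)

FLAG_SOLID, FLAG_FLUID, FLAG_INLET, FLAG_OUTLET0 = 0, 1, 2, 3
# outlet flags: 3 = descending outlet, 4.. = branch outlets


@dataclass(frozen=True)
class FluidProps:
    """Blood treated as a Newtonian fluid."""

    density: float = 1060.0        # kg/m^3
    viscosity: float = 0.0035      # Pa s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


@dataclass(frozen=True)
class LatticeConfig:
    """Numerical settings of the lattice solver."""

    dx: float = 1.0e-3             # m
    tau: float = 0.75              # BGK relaxation time (stability: (0.5, 2))
    u_lat_peak: float = 0.05       # lattice speed at the inlet waveform peak
    n_cycles: int = 3
    samples_per_cycle: int = 16    # stored field snapshots per cycle

    def __post_init__(self) -> None:
        if not 0.5 < self.tau < 2.0:
            raise ValueError(f"tau={self.tau} outside the stable range (0.5, 2)")
        if not 0 < self.u_lat_peak < 0.3 / math.sqrt(3):
            raise ValueError("u_lat_peak violates the low-Mach requirement")
        if self.dx <= 0:
            raise ValueError("dx must be positive")


@dataclass
class VoxelLattice:
    """Voxelized lumen: cell flags plus region labels on a uniform grid."""

    dx: float                       # m
    origin: np.ndarray              # m, position of cell (0,0,0) center
    flags: np.ndarray               # (nx, ny, nz) uint8, FLAG_* / outlet ids
    region: np.ndarray              # 0 none, 1 TL, 2 FL
    branch: np.ndarray              # -1 or branch index
    inlet_normal: np.ndarray        # unit vector, flow direction into the domain

    @property
    def fluid_count(self) -> int:
        return int(np.count_nonzero(self.flags != FLAG_SOLID))

    @property
    def n_outlets(self) -> int:
        return int(self.flags.max(initial=0) - FLAG_OUTLET0 + 1) \
            if self.flags.max(initial=0) >= FLAG_OUTLET0 else 0

    def cell_centers(self, mask: np.ndarray) -> np.ndarray:
        idx = np.argwhere(mask)
        return self.origin + (idx + 0.5) * self.dx


def voxelize(model, dx: float, pad: int = 2) -> VoxelLattice:
    """Voxelize a dissected-aorta model (or a watertight trimesh) at spacing dx [m].

    Cells are classified by the model's analytic cross-section regions
    (flap-solid cells are walls); inlet and outlet faces are flagged from the
    cut planes; fluid pockets not connected to the inlet are removed.
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    if hasattr(model, "is_watertight"):          # a raw surface mesh
        return _voxelize_mesh(model, dx, pad)
    dx_mm = dx * 1000.0
    lo = model.centerline.points.min(axis=0)
    hi = model.centerline.points.max(axis=0)
    Rmax = float(model.wall_radius.max()) + dx_mm
    blen = max((b.length for b in model.branches), default=0.0)
    lo = lo - (Rmax + blen + pad * dx_mm)
    hi = hi + (Rmax + blen + pad * dx_mm)
    shape = np.ceil((hi - lo) / dx_mm).astype(int) + 1
    ii = [np.arange(s) for s in shape]
    centers = np.stack(np.meshgrid(*ii, indexing="ij"), axis=-1).reshape(-1, 3) \
        * dx_mm + lo + 0.5 * dx_mm
    labels, branch = model.classify_points(centers)
    labels = labels.reshape(shape)
    branch = branch.reshape(shape).astype(np.int16)
    flags = np.where((labels == 1) | (labels == 2), FLAG_FLUID,
                     FLAG_SOLID).astype(np.uint8)
    region = np.where(labels == 1, 1, np.where(labels == 2, 2, 0)).astype(np.uint8)

    # inlet / outlet faces from the cut planes (one-cell-thick caps)
    cl = model.centerline
    grid_pts = centers.reshape(tuple(shape) + (3,))

    def _cap(origin_pt, normal, flag, radius, inward):
        # one cell layer just inside the cut plane: fluid sits at d >= 0 of
        # an inward-pointing cap normal (inlet) and d <= 0 of an outward one
        rel = grid_pts - origin_pt
        d = rel @ normal
        if inward:
            mask = (d >= -1e-9) & (d <= 1.05 * dx_mm)
        else:
            mask = (d <= 1e-9) & (d >= -1.05 * dx_mm)
        r2 = np.einsum("...i,...i->...", rel, rel) - d ** 2
        mask &= r2 <= (radius + dx_mm) ** 2
        sel = mask & (flags != FLAG_SOLID)
        flags[sel] = flag

    _cap(cl.points[0], cl.tangents[0], FLAG_INLET, model.wall_radius[0],
         inward=True)
    _cap(cl.points[-1], cl.tangents[-1], FLAG_OUTLET0, model.wall_radius[-1],
         inward=False)
    for k, b in enumerate(model.branches):
        tip = b.origin + b.axis * b.length
        _cap(tip, b.axis, FLAG_OUTLET0 + 1 + k, b.radius, inward=False)

    flags = _remove_isolated(flags)
    region[flags == FLAG_SOLID] = 0
    return VoxelLattice(dx=dx, origin=(lo + 0.5 * dx_mm) / 1000.0,
                        flags=flags, region=region, branch=branch,
                        inlet_normal=np.asarray(cl.tangents[0], float))


def _voxelize_mesh(mesh, dx: float, pad: int) -> VoxelLattice:
    """Voxelize a watertight triangulated lumen surface (units mm)."""
    if not mesh.is_watertight:
        raise ValueError("lumen surface is not watertight")
    dx_mm = dx * 1000.0
    lo = mesh.bounds[0] - pad * dx_mm
    hi = mesh.bounds[1] + pad * dx_mm
    shape = np.ceil((hi - lo) / dx_mm).astype(int) + 1
    ii = [np.arange(s) for s in shape]
    centers = np.stack(np.meshgrid(*ii, indexing="ij"), axis=-1).reshape(-1, 3) \
        * dx_mm + lo + 0.5 * dx_mm
    inside = mesh.contains(centers).reshape(shape)
    flags = np.where(inside, FLAG_FLUID, FLAG_SOLID).astype(np.uint8)
    region = flags.copy()
    return VoxelLattice(dx=dx, origin=(lo + 0.5 * dx_mm) / 1000.0, flags=flags,
                        region=region,
                        branch=np.full(shape, -1, np.int16),
                        inlet_normal=np.array([0.0, 0.0, 1.0]))


def _remove_isolated(flags: np.ndarray) -> np.ndarray:
    """Keep only fluid connected (6-neighbourhood) to the inlet cells."""
    from scipy import ndimage
    fluid = flags != FLAG_SOLID
    lab, _ = ndimage.label(fluid)
    keep = np.unique(lab[(flags == FLAG_INLET)])
    keep = keep[keep > 0]
    if len(keep) == 0:
        return flags
    ok = np.isin(lab, keep)
    out = flags.copy()
    out[~ok] = FLAG_SOLID
    return out


@dataclass
class FlowField:
    """Sampled velocity/pressure fields on the lattice fluid cells."""

    lattice: VoxelLattice
    times: np.ndarray                    # s, sample times (all cycles)
    cycle: np.ndarray                    # cycle index per sample
    velocity: np.ndarray                 # (n_samples, n_fluid, 3) m/s
    pressure: np.ndarray                 # (n_samples, n_fluid) Pa
    fluid_index: np.ndarray              # (n_fluid, 3) int cell coordinates
    info: dict = field(default_factory=dict)

    @property
    def analysis_cycle(self) -> int:
        """Index of the cycle used for analysis (the last one)."""
        return int(self.cycle.max())

    def samples_of_cycle(self, cycle: int | None = None) -> np.ndarray:
        c = self.analysis_cycle if cycle is None else cycle
        return np.where(self.cycle == c)[0]


@njit(cache=True)
def _step(f, fprop, flags, nbr, cx, cy, cz, w, opp, omega,
          u_in, in_dir, rho_out):
    """One BGK stream-collide update on the packed fluid-cell arrays."""
    n = f.shape[0]
    # streaming (pull): fprop[i, q] = f[nbr[i,q], q] or bounce-back
    for i in range(n):
        for q in range(19):
            j = nbr[i, q]
            if j >= 0:
                fprop[i, q] = f[j, q]
            else:
                fprop[i, q] = f[i, opp[q]]
    # boundary closure + collision
    for i in range(n):
        flag = flags[i]
        if flag == 2:
            # Zou-He velocity inlet (inlet normal along +z): density from the
            # known populations, missing +z populations closed by
            # non-equilibrium bounce-back at the target velocity
            ux = u_in * in_dir[0]
            uy = u_in * in_dir[1]
            uz = u_in * in_dir[2]
            s_mid = 0.0
            s_neg = 0.0
            for q in range(19):
                if cz[q] == 0.0:
                    s_mid += fprop[i, q]
                elif cz[q] < 0.0:
                    s_neg += fprop[i, q]
            rho = (s_mid + 2.0 * s_neg) / (1.0 - uz)
            usq = ux * ux + uy * uy + uz * uz
            for q in range(19):
                if cz[q] > 0.0:
                    cu = cx[q] * ux + cy[q] * uy + cz[q] * uz
                    feq_q = w[q] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu
                                          - 1.5 * usq)
                    qb = opp[q]
                    cub = cx[qb] * ux + cy[qb] * uy + cz[qb] * uz
                    feq_b = w[qb] * rho * (1.0 + 3.0 * cub + 4.5 * cub * cub
                                           - 1.5 * usq)
                    fprop[i, q] = fprop[i, qb] + (feq_q - feq_b)
        rho = 0.0
        ux = 0.0
        uy = 0.0
        uz = 0.0
        for q in range(19):
            fq = fprop[i, q]
            rho += fq
            ux += fq * cx[q]
            uy += fq * cy[q]
            uz += fq * cz[q]
        ux /= rho
        uy /= rho
        uz /= rho
        if flag >= 3:       # outlet: prescribed density, local velocity
            rho = rho_out[flag - 3]
        usq = ux * ux + uy * uy + uz * uz
        for q in range(19):
            cu = cx[q] * ux + cy[q] * uy + cz[q] * uz
            feq = w[q] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)
            if flag >= 3:
                f[i, q] = feq
            else:
                f[i, q] = fprop[i, q] + omega * (feq - fprop[i, q])
    return f


def _pack(lattice: VoxelLattice):
    """Pack fluid cells and per-direction neighbour indices."""
    fluid = lattice.flags != FLAG_SOLID
    coords = np.argwhere(fluid)
    index_of = -np.ones(lattice.flags.shape, dtype=np.int64)
    index_of[tuple(coords.T)] = np.arange(len(coords))
    shape = lattice.flags.shape
    nbr = np.full((len(coords), 19), -1, dtype=np.int64)
    for q in range(19):
        src = coords - _C[q]          # pull scheme: where f_q streams from
        ok = np.all((src >= 0) & (src < shape), axis=1)
        vals = np.full(len(coords), -1, dtype=np.int64)
        vals[ok] = index_of[tuple(src[ok].T)]
        nbr[:, q] = vals
    return coords, nbr


def run_pulsatile_lbm(lattice: VoxelLattice, inlet: WaveformSpec,
                      outlet: WaveformSpec, props: FluidProps = FluidProps(),
                      config: LatticeConfig = LatticeConfig(),
                      n_cycles: int | None = None) -> FlowField:
    """Advance the pulsatile flow for ``n_cycles`` cardiac cycles.

    The inlet velocity magnitude follows the inlet waveform [m/s]; all
    outlets follow the outlet pressure waveform [Pa] (converted to lattice
    density around the waveform mean). Returns sampled fields for every
    cycle with the last cycle flagged for analysis.
    """
    n_cycles = config.n_cycles if n_cycles is None else n_cycles
    T = inlet.period
    t_probe = np.linspace(0, T, 512, endpoint=False)
    v_peak = float(np.abs(inlet(t_probe)).max())
    if v_peak <= 0:
        v_peak = 1e-6
    dt = config.u_lat_peak * lattice.dx / v_peak
    nu_lat = (config.tau - 0.5) / 3.0
    nu_eff = nu_lat * lattice.dx ** 2 / dt
    steps_per_cycle = max(int(round(T / dt)), 8)
    dt = T / steps_per_cycle
    u_scale = dt / lattice.dx                   # m/s -> lattice units
    if v_peak * u_scale > 0.3 / math.sqrt(3):
        raise ValueError("inlet waveform violates the low-Mach bound at this dt")
    p_ref = float(np.mean(outlet(t_probe)))
    cs2_phys = (lattice.dx / dt) ** 2 / 3.0 * props.density   # Pa per unit drho

    coords, nbr = _pack(lattice)
    flags_cell = lattice.flags[tuple(coords.T)].astype(np.int64)
    # map flag values: fluid 1 -> 0/1 irrelevant; inlet 2; outlets >= 3
    n = len(coords)
    f = np.tile((_W * 1.0), (n, 1))
    fprop = np.empty_like(f)
    cx, cy, cz = (_C[:, 0].astype(np.float64), _C[:, 1].astype(np.float64),
                  _C[:, 2].astype(np.float64))
    omega = 1.0 / config.tau
    in_dir = lattice.inlet_normal / np.linalg.norm(lattice.inlet_normal)
    n_out = max(lattice.n_outlets, 1)

    sample_steps = np.unique((np.arange(config.samples_per_cycle)
                              * steps_per_cycle // config.samples_per_cycle))
    times, cycles, vel_s, pres_s = [], [], [], []
    for cyc in range(n_cycles):
        for s in range(steps_per_cycle):
            t = cyc * T + s * dt
            u_in = float(inlet(t)) * u_scale
            rho_out = np.full(n_out, 1.0 + (float(outlet(t)) - p_ref)
                              / cs2_phys)
            f = _step(f, fprop, flags_cell, nbr, cx, cy, cz, _W, _OPP,
                      omega, u_in, in_dir, rho_out)
            if s in sample_steps:
                rho = f.sum(axis=1)
                u = (f @ _C.astype(float)) / rho[:, None] / u_scale
                p = (rho - 1.0) * cs2_phys + p_ref
                times.append(t)
                cycles.append(cyc)
                vel_s.append(u.astype(np.float32))
                pres_s.append(p.astype(np.float32))
    if not np.all(np.isfinite(pres_s[-1])):
        raise FloatingPointError("lattice solution diverged (non-finite fields)")
    info = {"dt": dt, "steps_per_cycle": steps_per_cycle, "nu_eff": nu_eff,
            "nu_physical": props.kinematic_viscosity,
            "reynolds_scale": props.kinematic_viscosity / nu_eff,
            "fluid_cells": n, "tau": config.tau, "p_ref": p_ref}
    return FlowField(lattice=lattice, times=np.array(times),
                     cycle=np.array(cycles), velocity=np.array(vel_s),
                     pressure=np.array(pres_s), fluid_index=coords, info=info)
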