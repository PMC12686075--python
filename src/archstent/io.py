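"""Plain-text writers for simulation products (legacy ASCII VTK, CSV, STL).

The VTK writers emit legacy (version 2.0) ASCII files readable by ParaView:
polyline/line sets for wire meshes and centerlines, unstructured grids for
deployment snapshots, and structured points for lattice flow fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_vtk_lines", "write_vtk_triangles", "write_vtk_structured",
           "write_centerline_txt"]


def _header(fh, title: str, dataset: str) -> None:
    fh.write("# vtk DataFile Version 2.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\n")
    fh.write(f"DATASET {dataset}\n")


def _points(fh, pts: np.ndarray) -> None:
    fh.write(f"POINTS {len(pts)} float\n")
    np.savetxt(fh, np.asarray(pts, float), fmt="%.6f")


def _cell_data(fh, n_cells: int, cell_data: dict | None) -> None:
    if not cell_data:
        return
    fh.write(f"CELL_DATA {n_cells}\n")
    for name, values in cell_data.items():
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, np.asarray(values, float), fmt="%.6g")


def write_vtk_lines(path, points: np.ndarray, lines: np.ndarray,
                    cell_data: dict | None = None, title: str = "wire mesh") -> None:
    """Line/segment cells (e.g. beam elements) with optional per-cell scalars."""
    lines = np.atleast_2d(np.asarray(lines, int))
    with open(path, "w") as fh:
        _header(fh, title, "POLYDATA")
        _points(fh, points)
        fh.write(f"LINES {len(lines)} {len(lines) * 3}\n")
        for a, b in lines:
            fh.write(f"2 {a} {b}\n")
        _cell_data(fh, len(lines), cell_data)


def write_vtk_triangles(path, points: np.ndarray, faces: np.ndarray,
                        cell_data: dict | None = None, title: str = "surface") -> None:
    faces = np.atleast_2d(np.asarray(faces, int))
    with open(path, "w") as fh:
        _header(fh, title, "POLYDATA")
        _points(fh, points)
        fh.write(f"POLYGONS {len(faces)} {len(faces) * 4}\n")
        for a, b, c in faces:
            fh.write(f"3 {a} {b} {c}\n")
        _cell_data(fh, len(faces), cell_data)


def write_vtk_structured(path, field, sample: int, title: str = "flow") -> None:
    """One flow-field snapshot as STRUCTURED_POINTS with velocity + pressure."""
    lat = field.lattice
    shape = lat.flags.shape
    with open(path, "w") as fh:
        _header(fh, title, "STRUCTURED_POINTS")
        fh.write(f"DIMENSIONS {shape[0]} {shape[1]} {shape[2]}\n")
        o = lat.origin
        fh.write(f"ORIGIN {o[0]:.6e} {o[1]:.6e} {o[2]:.6e}\n")
        fh.write(f"SPACING {lat.dx:.6e} {lat.dx:.6e} {lat.dx:.6e}\n")
        n = int(np.prod(shape))
        fh.write(f"POINT_DATA {n}\n")
        pres = np.zeros(shape, np.float32)
        vel = np.zeros(shape + (3,), np.float32)
        ix = tuple(field.fluid_index.T)
        pres[ix] = field.pressure[sample]
        vel[ix] = field.velocity[sample]
        fh.write("SCALARS pressure float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, pres.reshape(-1, order="F"), fmt="%.6g")
        fh.write("VECTORS velocity float\n")
        np.savetxt(fh, vel.reshape(-1, 3, order="F"), fmt="%.6g")


def write_centerline_txt(path, centerline) -> None:
    """Centerline as plain text rows: x y z [mm]."""
    np.savetxt(path, centerline.points, fmt="%.6f", header="x y z (mm)")
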