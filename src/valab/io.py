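"""Readers and writers for surface meshes and per-vertex scalar maps.

Formats: legacy ASCII VTK polydata (with point-data scalars and cell-data
fiber vectors), PLY (via trimesh), the CARP-style .pts/.elem/.lon plain-text
triplet, and one-value-per-line per-vertex .dat files.
"""

from __future__ import annotations

import os

import numpy as np
import trimesh

from .synthetic_cohort import AtrialSurface, _boundary_loops_of


def write_vtk(path: str, surface: AtrialSurface, point_data: dict | None = None,
              cell_vectors: dict | None = None) -> None:
    """Legacy ASCII VTK polydata with optional per-vertex scalar arrays."""
    v, t = surface.vertices, surface.triangles
    lines = ["# vtk DataFile Version 3.0", "valab surface", "ASCII",
             "DATASET POLYDATA", f"POINTS {len(v)} float"]
    lines += [f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in v]
    lines.append(f"POLYGONS {len(t)} {4 * len(t)}")
    lines += [f"3 {a} {b} {c}" for a, b, c in t]
    point_data = dict(point_data or {})
    point_data.setdefault("region_label", surface.region_label)
    point_data.setdefault("coord1", surface.surf_coord[:, 0])
    point_data.setdefault("coord2", surface.surf_coord[:, 1])
    if point_data:
        lines.append(f"POINT_DATA {len(v)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            kind = "int" if np.issubdtype(arr.dtype, np.integer) else "float"
            lines.append(f"SCALARS {name} {kind} 1")
            lines.append("LOOKUP_TABLE default")
            fmt = "{:d}" if kind == "int" else "{:.6f}"
            lines += [fmt.format(x) for x in arr]
    cell_vectors = dict(cell_vectors or {})
    cell_vectors.setdefault("fiber", surface.fiber)
    if cell_vectors:
        lines.append(f"CELL_DATA {len(t)}")
        for name, arr in cell_vectors.items():
            lines.append(f"VECTORS {name} float")
            lines += [f"{a:.6f} {b:.6f} {c:.6f}" for a, b, c in np.asarray(arr)]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk(path: str):
    """Read back a legacy VTK polydata written by :func:`write_vtk`.

    Returns ``(vertices, triangles, point_data, cell_vectors)``.
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    i = 0
    verts = tris = None
    point_data, cell_vectors = {}, {}
    n_points = n_cells = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n_points = int(line.split()[1])
            vals = [tokens[i + 1 + k].split() for k in range(n_points)]
            verts = np.array(vals, dtype=float)
            i += n_points
        elif line.startswith("POLYGONS"):
            n_cells = int(line.split()[1])
            vals = [tokens[i + 1 + k].split()[1:] for k in range(n_cells)]
            tris = np.array(vals, dtype=int)
            i += n_cells
        elif line.startswith("SCALARS"):
            name, kind = line.split()[1:3]
            dtype = int if kind == "int" else float
            vals = [dtype(tokens[i + 2 + k]) for k in range(n_points)]
            point_data[name] = np.array(vals)
            i += n_points + 1
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            vals = [tokens[i + 1 + k].split() for k in range(n_cells)]
            cell_vectors[name] = np.array(vals, dtype=float)
            i += n_cells
        i += 1
    return verts, tris, point_data, cell_vectors


def write_ply(path: str, surface: AtrialSurface) -> None:
    mesh = trimesh.Trimesh(vertices=surface.vertices, faces=surface.triangles,
                           process=False)
    mesh.export(path, file_type="ply", encoding="ascii")


def write_carp(prefix: str, surface: AtrialSurface) -> None:
    """CARP-style .pts / .elem / .lon triplet."""
    with open(prefix + ".pts", "w") as fh:
        fh.write(f"{len(surface.vertices)}\n")
        for x, y, z in surface.vertices:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
    with open(prefix + ".elem", "w") as fh:
        fh.write(f"{len(surface.triangles)}\n")
        reg = surface.region_label[surface.triangles]
        elem_reg = np.array([np.bincount(r, minlength=6).argmax() for r in reg])
        for (a, b, c), r in zip(surface.triangles, elem_reg):
            fh.write(f"Tr {a} {b} {c} {r}\n")
    with open(prefix + ".lon", "w") as fh:
        fh.write("1\n")
        for a, b, c in surface.fiber:
            fh.write(f"{a:.6f} {b:.6f} {c:.6f}\n")


def read_carp(prefix: str):
    """Read a .pts/.elem/.lon triplet; returns (vertices, triangles, fibers)."""
    with open(prefix + ".pts") as fh:
        n = int(fh.readline())
        verts = np.array([fh.readline().split() for _ in range(n)], dtype=float)
    with open(prefix + ".elem") as fh:
        n = int(fh.readline())
        tris = np.array([fh.readline().split()[1:4] for _ in range(n)], dtype=int)
    fibers = None
    if os.path.exists(prefix + ".lon"):
        with open(prefix + ".lon") as fh:
            fh.readline()
            fibers = np.array([l.split() for l in fh if l.strip()], dtype=float)
    return verts, tris, fibers


def write_dat(path: str, values) -> None:
    """One value per line, vertex order (CARP .dat dialect)."""
    np.savetxt(path, np.asarray(values), fmt="%.8g")


def read_dat(path: str) -> np.ndarray:
    return np.loadtxt(path)


def surface_from_arrays(vertices: np.ndarray, triangles: np.ndarray,
                        region_label=None, surf_coord=None,
                        fiber=None) -> AtrialSurface:
    """Assemble an AtrialSurface from raw arrays (labels default to body)."""
    nv, nt = len(vertices), len(triangles)
    if region_label is None:
        region_label = np.zeros(nv, dtype=int)
    if surf_coord is None:
        surf_coord = np.zeros((nv, 2))
    if fiber is None:
        fiber = np.tile([1.0, 0.0, 0.0], (nt, 1))
    edges = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]],
                       triangles[:, [2, 0]]])
    edges.sort(axis=1)
    edges = np.unique(edges, axis=0)
    elen = float(np.linalg.norm(vertices[edges[:, 0]] - vertices[edges[:, 1]],
                                axis=1).mean())
    unit = vertices / np.linalg.norm(vertices, axis=1, keepdims=True).clip(1e-12)
    return AtrialSurface(vertices=np.asarray(vertices, dtype=float),
                         triangles=np.asarray(triangles, dtype=int),
                         region_label=np.asarray(region_label, dtype=int),
                         boundary_loops=_boundary_loops_of(np.asarray(triangles)),
                         surf_coord=np.asarray(surf_coord, dtype=float),
                         fiber=np.asarray(fiber, dtype=float),
                         unit_dirs=unit, target_edge_length=elen)
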