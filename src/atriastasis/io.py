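"""File I/O: legacy-VTK ASCII, STL, NIfTI masks and JSON sidecars.

Surface series are written as one legacy-VTK polydata file per phase
(lines for 2D polylines, triangles via STL/trimesh for the extruded 3D
mode) next to a JSON sidecar holding phase fractions, the RR interval,
the extrusion depth and the edge-label map.  Binary masks go to NIfTI
(2D stacks are stored as nx × ny × phases volumes with the pixel spacing
in the affine).  The VTK writer/reader covers exactly the subset of the
legacy format this package produces.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from .geometry import MaskStack, PhaseLoop, SurfaceSeries

__all__ = [
    "write_vtk_polyline",
    "read_vtk_polyline",
    "write_vtk_triangles",
    "write_series",
    "read_series",
    "write_masks_nifti",
]


def write_vtk_polyline(
    path,
    points: np.ndarray,
    closed: bool = True,
    point_data: Optional[Dict[str, np.ndarray]] = None,
) -> None:
    """Write a polyline (2D points get z = 0) as legacy-VTK polydata."""
    points = np.asarray(points, dtype=float)
    if points.shape[1] == 2:
        points = np.column_stack([points, np.zeros(len(points))])
    n = len(points)
    ids = list(range(n)) + ([0] if closed else [])
    lines = [
        "# vtk DataFile Version 3.0",
        "atriastasis surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in points]
    lines.append(f"LINES 1 {len(ids) + 1}")
    lines.append(" ".join(map(str, [len(ids)] + ids)))
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.9g}" for v in arr]
            else:
                if arr.shape[1] == 2:
                    arr = np.column_stack([arr, np.zeros(len(arr))])
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{v:.9g}" for v in row) for row in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_polyline(path) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    """Read back a polyline written by :func:`write_vtk_polyline`.

    Returns the (n, 2) points (z dropped) and any point-data arrays.
    """
    tokens = Path(path).read_text().split("\n")
    i = 0
    points = None
    data: Dict[str, np.ndarray] = {}
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            pts = [
                [float(v) for v in tokens[i + 1 + j].split()] for j in range(n)
            ]
            points = np.asarray(pts)[:, :2]
            i += n + 1
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            n = len(points)
            vals = [float(tokens[i + 2 + j]) for j in range(n)]
            data[name] = np.asarray(vals)
            i += n + 2
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            n = len(points)
            vals = [
                [float(v) for v in tokens[i + 1 + j].split()] for j in range(n)
            ]
            data[name] = np.asarray(vals)[:, :2]
            i += n + 1
        else:
            i += 1
    if points is None:
        raise ValueError(f"{path}: no POINTS section found")
    return points, data


def write_vtk_triangles(
    path,
    points: np.ndarray,
    triangles: np.ndarray,
    point_data: Optional[Dict[str, np.ndarray]] = None,
    cell_data: Optional[Dict[str, np.ndarray]] = None,
) -> None:
    """Write a triangle mesh (2D or 3D points) as legacy-VTK
    unstructured grid with optional nodal/cell fields."""
    points = np.asarray(points, dtype=float)
    if points.shape[1] == 2:
        points = np.column_stack([points, np.zeros(len(points))])
    triangles = np.asarray(triangles, dtype=int)
    n, m = len(points), len(triangles)
    lines = [
        "# vtk DataFile Version 3.0",
        "atriastasis mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in points]
    lines.append(f"CELLS {m} {4 * m}")
    lines += ["3 " + " ".join(map(str, t)) for t in triangles]
    lines.append(f"CELL_TYPES {m}")
    lines += ["5"] * m

    def emit(section: str, count: int, fields: Dict[str, np.ndarray]):
        lines.append(f"{section} {count}")
        for name, arr in fields.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in arr)
            else:
                if arr.shape[1] == 2:
                    arr = np.column_stack([arr, np.zeros(len(arr))])
                lines.append(f"VECTORS {name} double")
                lines.extend(" ".join(f"{v:.9g}" for v in row) for row in arr)

    if point_data:
        emit("POINT_DATA", n, point_data)
    if cell_data:
        emit("CELL_DATA", m, cell_data)
    Path(path).write_text("\n".join(lines) + "\n")


def write_series(series: SurfaceSeries, out_dir, fmt: str = "vtk") -> Path:
    """Write a surface series as per-phase files plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for comp, loop in series.loops.items():
        for k in range(series.phase_count):
            if fmt == "vtk" or series.dimension == 2:
                write_vtk_polyline(
                    out / f"{comp}_phase{k:02d}.vtk", loop.polyline(k)
                )
            elif fmt == "stl":
                series.to_trimesh(comp, k).export(
                    out / f"{comp}_phase{k:02d}.stl"
                )
            else:
                raise ValueError(f"unknown format {fmt!r}")
    sidecar = {
        "phase_fractions": series.phase_fractions.tolist(),
        "rr_interval": series.rr_interval,
        "depth": series.depth,
        "dimension": series.dimension,
        "edge_labels": {
            comp: loop.edge_labels.tolist()
            for comp, loop in series.loops.items()
        },
        "ostium_points": series.ostium_points.tolist(),
        "ostium_normal": series.ostium_normal.tolist(),
        "valve_points": series.valve_points.tolist(),
    }
    (out / "series.json").write_text(json.dumps(sidecar, indent=1))
    return out


def read_series(in_dir) -> SurfaceSeries:
    """Reassemble a surface series written by :func:`write_series`."""
    src = Path(in_dir)
    meta = json.loads((src / "series.json").read_text())
    loops = {}
    P = len(meta["phase_fractions"])
    for comp, labels in meta["edge_labels"].items():
        phases = [
            read_vtk_polyline(src / f"{comp}_phase{k:02d}.vtk")[0]
            for k in range(P)
        ]
        loops[comp] = PhaseLoop(
            vertices=np.stack(phases), edge_labels=np.asarray(labels)
        )
    return SurfaceSeries(
        loops=loops,
        phase_fractions=np.asarray(meta["phase_fractions"]),
        rr_interval=meta["rr_interval"],
        depth=meta["depth"],
        valve_points=np.asarray(meta["valve_points"]),
        ostium_points=np.asarray(meta["ostium_points"]),
        ostium_normal=np.asarray(meta["ostium_normal"]),
        dimension=meta["dimension"],
    )


def write_masks_nifti(masks: MaskStack, path) -> None:
    """Binary mask stack to NIfTI: (nx, ny, phases) with mm spacing."""
    import nibabel as nib

    vol = np.transpose(masks.masks.astype(np.uint8), (2, 1, 0))
    affine = np.diag([masks.spacing, masks.spacing, 1.0, 1.0])
    affine[0, 3], affine[1, 3] = masks.origin
    nib.save(nib.Nifti1Image(vol, affine), str(path))
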