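"""Graded 2D triangular meshing of closed chamber cross-sections.

Meshes are refined toward the wall: boundary edges are resampled at the
wall edge length, interior points are laid down on successive inward
offsets of the boundary with a spacing that grows geometrically up to the
maximum edge length, and the point cloud is triangulated with a Delaunay
pass restricted to the domain polygon.  Boundary vertices are kept first
in the point array, in traversal order, so boundary edge ``j`` connects
nodes ``j -> (j+1) % n_boundary`` and carries the label of the input edge
it came from.  An optional set of internal line points (the mitral valve
chord) is inserted verbatim so valves can be switched at the facet level
without touching the topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon

from .geometry import polygon_area, resample_polyline

__all__ = ["Mesh2D", "MeshingError", "build_mesh", "triangulate_polygon",
           "cross2"]


def cross2(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """z-component of the cross product of 2D vectors (vectorized)."""
    return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]


class MeshingError(ValueError):
    """Raised when a boundary cannot be meshed (self-intersection,
    inverted cells, non-conforming Delaunay pass)."""


@dataclass
class Mesh2D:
    """Triangulation of a closed planar domain (coordinates in mm)."""

    points: np.ndarray  # (n, 2)
    triangles: np.ndarray  # (m, 3) CCW
    n_boundary: int  # boundary nodes are points[:n_boundary], in loop order
    boundary_labels: np.ndarray  # (n_boundary,) label of edge j -> j+1
    valve_nodes: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_cells(self) -> int:
        return len(self.triangles)

    def cell_areas(self, points: Optional[np.ndarray] = None) -> np.ndarray:
        p = self.points if points is None else points
        a, b, c = (p[self.triangles[:, i]] for i in range(3))
        return 0.5 * cross2(b - a, c - a)

    @property
    def area(self) -> float:
        return float(self.cell_areas().sum())

    def boundary_edges(self) -> np.ndarray:
        n = self.n_boundary
        idx = np.arange(n)
        return np.column_stack([idx, (idx + 1) % n])

    def boundary_nodes_with_label(self, *labels: str) -> np.ndarray:
        """Nodes incident to any boundary edge carrying one of ``labels``."""
        sel = np.isin(self.boundary_labels, labels)
        edges = self.boundary_edges()[sel]
        return np.unique(edges)


def _resample_labelled_boundary(
    points: np.ndarray, labels: np.ndarray, spacing: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Resample a labelled closed polyline run-by-run so label-change
    points (cap corners, commissures) are preserved exactly."""
    n = len(points)
    labels = np.asarray(labels)
    change = np.nonzero(labels != np.roll(labels, 1))[0]
    if len(change) == 0:  # single label all around
        out = resample_polyline(points, spacing, closed=True)
        return out, np.full(len(out), labels[0])
    k = change[0]
    points = np.roll(points, -k, axis=0)
    labels = np.roll(labels, -k)
    verts, labs = [], []
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        run = points[i : j + 1] if j < n else np.vstack([points[i:], points[:1]])
        res = resample_polyline(run, spacing)
        verts.append(res[:-1])
        labs.extend([labels[i]] * (len(res) - 1))
        i = j
    return np.vstack(verts), np.array(labs)


def _hex_lattice(poly: Polygon, h: float) -> np.ndarray:
    """Triangular lattice at spacing ``h`` clipped to a polygon."""
    minx, miny, maxx, maxy = poly.bounds
    dy = h * np.sqrt(3) / 2
    rows = []
    j = 0
    y = miny
    while y <= maxy:
        xs = np.arange(minx + (h / 2 if j % 2 else 0.0), maxx + h, h)
        rows.append(np.column_stack([xs, np.full(len(xs), y)]))
        y += dy
        j += 1
    if not rows:
        return np.empty((0, 2))
    cand = np.vstack(rows)
    keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
    return cand[keep]


def _interior_points(
    poly: Polygon, wall_h: float, max_h: float, growth: float = 1.35
) -> np.ndarray:
    """Graded interior points: inward offset rings with spacing growing
    from ``wall_h`` to ``max_h``, then a uniform triangular lattice fill
    of the remaining core so thin/medial regions are never left empty."""
    pts = []
    h = wall_h
    d = 0.75 * wall_h
    while h < max_h * 0.999:
        inner = poly.buffer(-d)
        if inner.is_empty:
            break
        for g in getattr(inner, "geoms", [inner]):
            ring = np.asarray(g.exterior.coords[:-1])
            if len(ring) >= 3:
                pts.append(resample_polyline(ring, h, closed=True))
        h = min(h * growth, max_h)
        d += 0.85 * h
    core = poly.buffer(-d)
    if not core.is_empty:
        lattice = _hex_lattice(core, max_h)
        if len(lattice):
            if pts:
                ring_pts = np.vstack(pts)
                dmin, _ = cKDTree(ring_pts).query(lattice)
                lattice = lattice[dmin > 0.55 * max_h]
            pts.append(lattice)
    if not pts:
        return np.empty((0, 2))
    return np.vstack(pts)


def build_mesh(
    boundary: np.ndarray,
    boundary_labels: Optional[Sequence[str]] = None,
    wall_edge_length: float = 1.0,
    max_edge_length: float = 2.5,
    internal_points: Optional[np.ndarray] = None,
    resample_boundary: bool = True,
) -> Mesh2D:
    """Triangulate the closed CCW polyline ``boundary``.

    Parameters follow the production-solver convention (finer cells at the
    wall, coarser in the core) with defaults rescaled for the 2D desk mode;
    see the methods note for the scale factor.  Raises
    :class:`MeshingError` on a self-intersecting boundary, on inverted
    cells, or when the restricted Delaunay pass fails to conform to the
    boundary (e.g. a feature narrower than the wall edge length).
    """
    boundary = np.asarray(boundary, dtype=float)
    if boundary_labels is None:
        boundary_labels = np.full(len(boundary), "wall")
    if polygon_area(boundary) <= 0:
        raise MeshingError("boundary must be counter-clockwise (signed area > 0)")
    poly = Polygon(boundary)
    if not poly.is_valid or not poly.is_simple:
        raise MeshingError("boundary polygon is self-intersecting or invalid")

    if resample_boundary:
        bpts, blabels = _resample_labelled_boundary(
            boundary, np.asarray(boundary_labels), wall_edge_length
        )
    else:
        bpts, blabels = boundary, np.asarray(boundary_labels)
    nb = len(bpts)

    fixed = [bpts]
    n_valve = 0
    if internal_points is not None and len(internal_points):
        internal_points = np.asarray(internal_points, float)
        n_valve = len(internal_points)
        fixed.append(internal_points)
    fixed_pts = np.vstack(fixed)

    interior = _interior_points(poly, wall_edge_length, max_edge_length)
    if len(interior):
        # keep interior points clear of boundary and valve-line points
        tree = cKDTree(fixed_pts)
        dmin, _ = tree.query(interior)
        interior = interior[dmin > 0.6 * wall_edge_length]

    pts = np.vstack([fixed_pts, interior]) if len(interior) else fixed_pts
    n_fixed = nb + n_valve

    def inward_normal(j: int) -> np.ndarray:
        t = bpts[(j + 1) % nb] - bpts[(j - 1) % nb]
        n = np.array([-t[1], t[0]])  # left of CCW travel = inward
        norm = np.linalg.norm(n)
        return n / norm if norm > 0 else np.array([0.0, 0.0])

    # triangulate; if a fixed node or boundary edge ends up uncovered
    # (stretched boundary spacing, sharp concavity), drop a helper point
    # just inside the boundary there and retry
    cells = None
    for _attempt in range(4):
        tri = Delaunay(pts)
        cand = tri.simplices
        centroids = pts[cand].mean(axis=1)
        keep = shapely.contains_xy(poly, centroids[:, 0], centroids[:, 1])
        cand = cand[keep]
        if len(cand) == 0:
            raise MeshingError("no triangles inside the domain")
        a, b, c = (pts[cand[:, i]] for i in range(3))
        areas = 0.5 * cross2(b - a, c - a)
        flip = areas < 0
        cand[flip] = cand[flip][:, ::-1]
        cand = cand[np.abs(areas) > 1e-9 * np.median(np.abs(areas))]
        used = np.unique(cand)
        missing_nodes = np.setdiff1d(np.arange(n_fixed), used)
        edges_sorted = np.sort(
            np.concatenate(
                [cand[:, [0, 1]], cand[:, [1, 2]], cand[:, [2, 0]]], axis=0
            ),
            axis=1,
        )
        edge_set = set(map(tuple, edges_sorted))
        idx = np.arange(nb)
        want = np.sort(np.column_stack([idx, (idx + 1) % nb]), axis=1)
        missing_edges = [tuple(e) for e in want if tuple(e) not in edge_set]
        if len(missing_nodes) == 0 and not missing_edges:
            cells = cand
            break
        fixes = []
        for j in missing_nodes[missing_nodes < nb]:
            h_loc = np.linalg.norm(bpts[(j + 1) % nb] - bpts[j])
            fixes.append(bpts[j] + 0.4 * h_loc * inward_normal(int(j)))
        for (ea, eb) in missing_edges:
            if ea < nb and eb < nb:
                mid = 0.5 * (bpts[ea] + bpts[eb])
                h_loc = np.linalg.norm(bpts[eb] - bpts[ea])
                fixes.append(mid + 0.35 * h_loc * inward_normal(int(ea)))
        fixes = [
            f for f in fixes if shapely.contains_xy(poly, f[0], f[1])
        ]
        if not fixes:
            break
        pts = np.vstack([pts, np.asarray(fixes)])
    if cells is None:
        raise MeshingError(
            f"triangulation does not conform to the boundary "
            f"(uncovered nodes {missing_nodes[:5]}, edges {missing_edges[:5]})"
        )

    # drop unused points (beyond the fixed block) and remap
    used = np.unique(cells)
    remap = -np.ones(len(pts), dtype=int)
    remap[used] = np.arange(len(used))
    pts = pts[used]
    cells = remap[cells]

    valve_nodes = np.arange(nb, nb + n_valve)
    return Mesh2D(
        points=pts,
        triangles=cells,
        n_boundary=nb,
        boundary_labels=blabels,
        valve_nodes=valve_nodes,
    )


def triangulate_polygon(boundary: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Triangulate a closed CCW polyline (used for prism caps in the
    coarse 3D mode).  Returns ``(points, triangles)`` with the boundary
    vertices first, in their input order."""
    boundary = np.asarray(boundary, float)
    seg = np.linalg.norm(np.diff(boundary, axis=0), axis=1)
    h = float(np.median(seg)) if len(seg) else 1.0
    mesh = build_mesh(
        boundary,
        wall_edge_length=h,
        max_edge_length=3 * h,
        resample_boundary=False,
    )
    return mesh.points, mesh.triangles
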