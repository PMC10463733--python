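"""Morphological and functional cardiac descriptors.

Chamber volumes over the cycle, ejection fractions, LV stroke volume,
peak transvalvular flow rates, body-surface-area indexed variants, the LA
retention ratio (maximum atrial volume over ventricular stroke volume —
how much blood the atrium can hold relative to how much passes per beat),
and the ostium-plane split of the appendage from the atrial body.

Volumes come from the divergence theorem: in 2D desk mode the signed
polygon (shoelace) area of the closed boundary times the extrusion depth,
in 3D the signed volume of the closed triangulated surface.  A negative
signed result flags an inward-oriented boundary and is treated as an
error rather than silently negated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from shapely.geometry import LineString, Polygon
from shapely.ops import split as shapely_split

from .geometry import SurfaceSeries, polygon_area

__all__ = [
    "OstiumPlane",
    "DescriptorSet",
    "mesh_volume",
    "ejection_fraction",
    "retention_ratio",
    "index_by_bsa",
    "flow_rates",
    "split_laa",
    "compute_descriptors",
    "TABLE_FIELDS",
]


@dataclass
class OstiumPlane:
    """Cut plane (a line in 2D) at the narrowest point of the appendage
    neck; ``normal`` points into the appendage and is normalized."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("ostium plane normal must be non-zero")
        self.normal = n / norm

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - self.point) @ self.normal


def mesh_volume(boundary, depth: Optional[float] = None) -> float:
    """Enclosed volume (ml) of a closed, outward-oriented boundary.

    2D: a closed CCW polyline ``(n, 2)`` plus the extrusion ``depth`` in
    mm.  3D: a watertight ``trimesh.Trimesh`` (or anything exposing
    ``is_watertight``/``volume``).  Raises on open surfaces and on
    negative signed volume (inward orientation).
    """
    if hasattr(boundary, "volume") and hasattr(boundary, "is_watertight"):
        if not boundary.is_watertight:
            raise ValueError("surface mesh is not closed (watertight)")
        vol = float(boundary.volume)
        if vol <= 0:
            raise ValueError(
                "negative signed volume: boundary is inward-oriented"
            )
        return vol / 1000.0
    pts = np.asarray(boundary, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("2D boundary must be a closed polyline of shape (n, 2)")
    if not Polygon(pts).is_valid:
        raise ValueError("boundary polyline self-intersects")
    if depth is None:
        raise ValueError("2D boundaries need an extrusion depth (mm)")
    area = polygon_area(pts)
    if area <= 0:
        raise ValueError("negative signed area: boundary is inward-oriented")
    return area * depth / 1000.0


def ejection_fraction(v_max: float, v_min: float) -> float:
    """Ejection fraction in percent, ``100 * (v_max - v_min) / v_max``."""
    if v_max <= 0:
        raise ValueError(f"v_max must be > 0, got {v_max}")
    if v_min < 0:
        raise ValueError(f"v_min must be >= 0, got {v_min}")
    if v_min > v_max:
        raise ValueError(f"v_min ({v_min}) exceeds v_max ({v_max})")
    return 100.0 * (v_max - v_min) / v_max


def retention_ratio(la_max_vol: float, lv_sv: float) -> float:
    """LA retention ratio: maximum atrial volume / ventricular stroke
    volume (dimensionless)."""
    if lv_sv <= 0:
        raise ValueError(f"stroke volume must be > 0, got {lv_sv}")
    return la_max_vol / lv_sv


def index_by_bsa(value: float, bsa: float) -> float:
    """Index a volume by body surface area (ml -> ml/m²)."""
    if bsa <= 0:
        raise ValueError(f"bsa must be > 0, got {bsa}")
    return value / bsa


def flow_rates(volume_curve: np.ndarray, rr_interval: float) -> Tuple[float, float]:
    """Peak mitral and aortic flow (ml/s) from a periodic LV volume curve.

    The curve holds per-phase LV volumes (ml) at uniform fractions of the
    cycle; its time derivative comes from a periodic cubic spline.  Flows
    are signed positive in the physiologic direction, so the mitral peak
    is the largest filling rate (+dV/dt) and the aortic peak the largest
    ejection rate (-dV/dt).  Returns ``(peak_mitral, peak_aortic)``.
    """
    v = np.asarray(volume_curve, dtype=float)
    if v.ndim != 1 or len(v) < 4:
        raise ValueError("volume curve needs at least 4 phases")
    if rr_interval <= 0:
        raise ValueError("rr_interval must be > 0")
    t = np.arange(len(v) + 1) / len(v) * rr_interval
    spline = CubicSpline(t, np.append(v, v[0]), bc_type="periodic")
    tt = np.linspace(0, rr_interval, 2000, endpoint=False)
    dv = spline(tt, 1)
    return float(np.max(dv)), float(np.max(-dv))


@dataclass
class LaaSplit:
    """Result of cutting the atrium at the ostium plane."""

    la_body_volume: float  # ml
    laa_volume: float  # ml
    laa_edges: np.ndarray  # bool mask over boundary edges (midpoint in LAA)


def split_laa(
    surface: np.ndarray, plane: OstiumPlane, depth: float
) -> LaaSplit:
    """Split a closed LA boundary into atrial body and appendage.

    The cut cross-section is capped, so the two part volumes sum to the
    total volume exactly.  Raises if the plane misses the surface, cuts
    off nothing, or separates more than one appendage component.
    """
    pts = np.asarray(surface, dtype=float)
    poly = Polygon(pts)
    s = plane.signed_distance(pts)
    if np.all(s <= 0) or np.all(s >= 0):
        raise ValueError("ostium plane does not intersect the surface")
    tangent = np.array([-plane.normal[1], plane.normal[0]])
    span = 10.0 * float(np.max(np.linalg.norm(pts - plane.point, axis=1)))
    cutter = LineString(
        [plane.point - span * tangent, plane.point + span * tangent]
    )
    pieces = [g for g in shapely_split(poly, cutter).geoms if g.area > 1e-9]
    laa_pieces = [
        g
        for g in pieces
        if (np.asarray(g.representative_point().coords[0]) - plane.point)
        @ plane.normal
        > 0
    ]
    if len(laa_pieces) == 0:
        raise ValueError("ostium plane leaves an empty appendage")
    if len(laa_pieces) > 1:
        raise ValueError(
            f"ostium plane separates {len(laa_pieces)} appendage components"
        )
    laa_area = laa_pieces[0].area
    body_area = sum(g.area for g in pieces) - laa_area
    mids = 0.5 * (pts + np.roll(pts, -1, axis=0))
    laa_edges = plane.signed_distance(mids) > 0
    return LaaSplit(
        la_body_volume=body_area * depth / 1000.0,
        laa_volume=laa_area * depth / 1000.0,
        laa_edges=laa_edges,
    )


# Column headers used in per-subject records; mirrors the layout of a
# two-group clinical descriptor table.
TABLE_FIELDS: Dict[str, str] = {
    "la_min_vol_idx": "LA Min Volume,Idx (ml/m^2)",
    "la_max_vol_idx": "LA Max Volume,Idx (ml/m^2)",
    "la_ef": "LA EF (%)",
    "laa_min_vol_idx": "LAA Min Volume,Idx (ml/m^2)",
    "laa_max_vol_idx": "LAA Max Volume,Idx (ml/m^2)",
    "laa_ef": "LAA EF (%)",
    "lv_esv_idx": "LV End Systolic Volume,Idx (ml/m^2)",
    "lv_edv_idx": "LV End Diastolic Volume,Idx (ml/m^2)",
    "lv_ef": "LV EF (%)",
    "lv_sv": "LV Stroke Volume (ml)",
    "la_retention_ratio": "LA retention ratio (-)",
}


@dataclass
class DescriptorSet:
    """Per-subject chamber descriptors (volumes ml, EFs percent)."""

    la_min_vol: float
    la_max_vol: float
    laa_min_vol: float
    laa_max_vol: float
    lv_esv: float
    lv_edv: float
    la_ef: float
    laa_ef: float
    lv_ef: float
    lv_sv: float
    peak_mitral_flow: float  # ml/s
    peak_aortic_flow: float  # ml/s
    la_retention_ratio: float
    bsa: float

    def __post_init__(self):
        for chamber, (vmin, vmax) in {
            "la": (self.la_min_vol, self.la_max_vol),
            "laa": (self.laa_min_vol, self.laa_max_vol),
            "lv": (self.lv_esv, self.lv_edv),
        }.items():
            if vmin > vmax:
                raise ValueError(f"{chamber}: min volume exceeds max volume")
        if abs(self.lv_sv - (self.lv_edv - self.lv_esv)) > 1e-9 * max(
            1.0, self.lv_edv
        ):
            raise ValueError("lv_sv must equal lv_edv - lv_esv")

    @property
    def indexed(self) -> Dict[str, float]:
        """BSA-indexed volumes (ml/m²)."""
        return {
            "la_min_vol_idx": index_by_bsa(self.la_min_vol, self.bsa),
            "la_max_vol_idx": index_by_bsa(self.la_max_vol, self.bsa),
            "laa_min_vol_idx": index_by_bsa(self.laa_min_vol, self.bsa),
            "laa_max_vol_idx": index_by_bsa(self.laa_max_vol, self.bsa),
            "lv_esv_idx": index_by_bsa(self.lv_esv, self.bsa),
            "lv_edv_idx": index_by_bsa(self.lv_edv, self.bsa),
        }

    def record(self) -> Dict[str, float]:
        """Flat record with table-style headers (for CSV emitters)."""
        idx = self.indexed
        values = {
            **idx,
            "la_ef": self.la_ef,
            "laa_ef": self.laa_ef,
            "lv_ef": self.lv_ef,
            "lv_sv": self.lv_sv,
            "la_retention_ratio": self.la_retention_ratio,
        }
        return {TABLE_FIELDS[k]: values[k] for k in TABLE_FIELDS}


def compute_descriptors(
    series: SurfaceSeries, bsa: Optional[float] = None
) -> DescriptorSet:
    """Extract the full descriptor set from a phase-resolved series.

    End-diastole and end-systole are identified as the phases of maximum
    and minimum LV volume.  The LA loop includes the appendage; appendage
    volumes use the stored ostium plane.
    """
    if bsa is None:
        bsa = series.spec.bsa if series.spec is not None else 1.0
    la = series.volume_curve("la")
    lv = series.volume_curve("lv")
    laa = np.array([series.laa_volume(k) for k in range(series.phase_count)])
    lv_edv, lv_esv = float(lv.max()), float(lv.min())
    sv = lv_edv - lv_esv
    peak_mitral, peak_aortic = flow_rates(lv, series.rr_interval)
    return DescriptorSet(
        la_min_vol=float(la.min()),
        la_max_vol=float(la.max()),
        laa_min_vol=float(laa.min()),
        laa_max_vol=float(laa.max()),
        lv_esv=lv_esv,
        lv_edv=lv_edv,
        la_ef=ejection_fraction(float(la.max()), float(la.min())),
        laa_ef=ejection_fraction(float(laa.max()), float(laa.min())),
        lv_ef=ejection_fraction(lv_edv, lv_esv),
        lv_sv=sv,
        peak_mitral_flow=peak_mitral,
        peak_aortic_flow=peak_aortic,
        la_retention_ratio=retention_ratio(float(la.max()), sv),
        bsa=bsa,
    )
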