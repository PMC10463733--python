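"""Synthetic left-heart geometry with prescribed periodic wall motion.

This module stands in for the segmentation stage of a CT-based stasis
pipeline: it builds idealized, parameterized 2D cross-sections of the left
atrium (LA), left atrial appendage (LAA) and left ventricle (LV), deforms
them through a cardiac cycle with physiologic volume waveforms (reservoir /
conduit / booster for the LA, systolic ejection and biphasic filling for
the LV), and samples synthetic cohorts whose parameter distributions mimic
a control group and a paroxysmal-AF group.

Geometry convention
-------------------
Coordinates are millimetres, right-handed, with the mitral valve plane on
``y = 0``; the LA sits above it and the LV below.  A 2D cross-section of
area ``A`` mm² represents a chamber of volume ``A * depth`` mm³ where
``depth`` is a fixed out-of-plane extrusion depth (default 40 mm).  All
boundary loops are closed, counter-clockwise (signed area > 0) polylines
with one label per edge; edge ``j`` connects vertex ``j`` to ``j+1``
(modulo the loop length).

Chamber volumes follow smooth piecewise-cosine waveforms; the deformation
at each phase is a radial scaling about the mitral-plane centre, blended
across the valve plane so the LA and LV scale factors meet continuously,
plus an extra scaling of the appendage pouch about its ostium.  The scale
factors are solved per phase so the prescribed chamber volumes are matched
essentially exactly, and phase 1.0 coincides with phase 0 by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import shapely
from scipy.optimize import brentq, root
from shapely.geometry import Polygon

__all__ = [
    "ChamberSpec",
    "CohortSpec",
    "SurfaceSeries",
    "MaskStack",
    "CycleTiming",
    "VolumeCurve",
    "generate_chamber_series",
    "generate_cohort",
    "voxelize",
    "DEFAULT_GROUP_DISTRIBUTIONS",
    "DEFAULT_CW_PROBABILITY",
]

# ---------------------------------------------------------------------------
# specs


@dataclass
class ChamberSpec:
    """Per-subject chamber parameters (absolute volumes in ml).

    ``laa_shape_label`` is carried as a categorical tag only; it does not
    alter the generated topology (no association between appendage shape
    class and stasis is built in).
    """

    la_max_volume: float = 87.0  # ml, includes the appendage
    la_ef: float = 0.53
    laa_max_volume: float = 6.8  # ml
    laa_ef: float = 0.72
    lv_edv: float = 145.0  # ml
    lv_esv: float = 47.0  # ml
    heart_rate: float = 67.0  # beats / min
    bsa: float = 2.13  # m^2
    laa_shape_label: str = "chicken_wing"
    phase_count: int = 20
    dimension: int = 2

    @property
    def rr_interval(self) -> float:
        """Cardiac period in seconds."""
        return 60.0 / self.heart_rate

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated invariant."""
        if not (0.05 < self.la_ef < 0.85):
            raise ValueError(
                f"la_ef must be in the plausible range (0.05, 0.85), got {self.la_ef}"
            )
        if not (0.05 < self.laa_ef < 0.92):
            raise ValueError(
                f"laa_ef must be in the plausible range (0.05, 0.92), got {self.laa_ef}"
            )
        for name in ("la_max_volume", "laa_max_volume", "lv_edv", "lv_esv"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not self.lv_esv < self.lv_edv:
            raise ValueError(
                f"lv_esv ({self.lv_esv}) must be smaller than lv_edv ({self.lv_edv})"
            )
        lv_ef = 1.0 - self.lv_esv / self.lv_edv
        if not (0.2 < lv_ef < 0.85):
            raise ValueError(
                f"implied LV EF {lv_ef:.2f} outside the plausible range (0.2, 0.85)"
            )
        if not (30.0 < self.heart_rate < 150.0):
            raise ValueError(
                f"heart_rate must be in (30, 150) bpm, got {self.heart_rate}"
            )
        if not (1.0 < self.bsa < 3.5):
            raise ValueError(f"bsa must be in (1.0, 3.5) m², got {self.bsa}")
        if self.phase_count < 4:
            raise ValueError(f"phase_count must be >= 4, got {self.phase_count}")
        if self.dimension not in (2, 3):
            raise ValueError(f"dimension must be 2 or 3, got {self.dimension}")
        if self.laa_max_volume >= 0.5 * self.la_max_volume:
            raise ValueError(
                "laa_max_volume must be below half of la_max_volume "
                f"({self.laa_max_volume} vs {self.la_max_volume})"
            )
        if self.laa_shape_label not in ("chicken_wing", "non_chicken_wing"):
            raise ValueError(f"unknown laa_shape_label {self.laa_shape_label!r}")


# Group parameter distributions (mean, SD).  Volumes are indexed by body
# surface area (ml/m^2), as clinical studies report them; absolute volumes
# are formed at draw time as idx * bsa.  EFs are fractions.
DEFAULT_GROUP_DISTRIBUTIONS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "control": {
        "bsa": (2.13, 0.28),
        "heart_rate": (67.0, 7.0),
        "la_max_volume_idx": (41.0, 7.0),
        "la_ef": (0.53, 0.07),
        "laa_max_volume_idx": (3.2, 1.3),
        "laa_ef": (0.72, 0.07),
        "lv_edv_idx": (68.0, 18.0),
        "lv_esv_idx": (22.0, 11.0),
    },
    "af": {
        "bsa": (2.02, 0.17),
        "heart_rate": (62.0, 8.0),
        "la_max_volume_idx": (66.0, 15.0),
        "la_ef": (0.43, 0.09),
        "laa_max_volume_idx": (6.0, 2.7),
        "laa_ef": (0.62, 0.12),
        "lv_edv_idx": (78.0, 11.0),
        "lv_esv_idx": (26.0, 6.0),
    },
}

# Fraction of chicken-wing appendage shapes per group (7/8 and 16/21).
DEFAULT_CW_PROBABILITY: Dict[str, float] = {"control": 7 / 8, "af": 16 / 21}


@dataclass
class CohortSpec:
    """Sampling plan for a synthetic two-group cohort.

    Draws are rejected and redrawn (up to ``max_redraws`` times per
    subject) whenever they violate a :class:`ChamberSpec` invariant, e.g.
    an EF outside (0, 1) from the tail of its normal distribution.
    """

    n_control: int = 8
    n_af: int = 21
    parameter_distributions: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=lambda: {
            g: dict(d) for g, d in DEFAULT_GROUP_DISTRIBUTIONS.items()
        }
    )
    cw_probability: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CW_PROBABILITY)
    )
    seed: int = 0
    max_redraws: int = 100

    def validate(self) -> None:
        if self.n_control < 0 or self.n_af < 0:
            raise ValueError("group sizes must be non-negative")
        for group, dists in self.parameter_distributions.items():
            for name, (mean, sd) in dists.items():
                if sd < 0:
                    raise ValueError(f"{group}.{name}: SD must be >= 0, got {sd}")
            for ef_name in ("la_ef", "laa_ef"):
                mean = dists[ef_name][0]
                if not (0.0 < mean < 1.0):
                    raise ValueError(
                        f"{group}.{ef_name}: mean EF must be in (0, 1), got {mean}"
                    )
            if dists["lv_esv_idx"][0] >= dists["lv_edv_idx"][0]:
                raise ValueError(f"{group}: mean ESV must be below mean EDV")


# ---------------------------------------------------------------------------
# volume waveforms


@dataclass
class CycleTiming:
    """Timing landmarks as fractions of the RR interval.

    ``systole_end`` is the instant of minimum LV volume (aortic valve
    closure), ``diastasis_start`` the end of early (passive) ventricular
    filling, ``atrial_kick_start`` the onset of active atrial contraction.
    ``passive_fraction`` is the share of LV filling (and of LA emptying)
    completed before diastasis.  These are documented synthetic defaults;
    any smooth periodic curve hitting the prescribed extreme volumes is an
    equally valid stand-in.
    """

    systole_end: float = 0.35
    diastasis_start: float = 0.65
    atrial_kick_start: float = 0.85
    passive_fraction: float = 0.65


class VolumeCurve:
    """Smooth periodic volume waveform built from half-cosine segments.

    Each segment runs between two knots ``(t0, v0) -> (t1, v1)`` (t in
    fractions of the cycle) along ``v0 + (v1-v0) * (1 - cos(pi*s)) / 2``,
    which has zero slope at both ends, so the assembled curve is C^1 and
    periodic by construction.
    """

    def __init__(self, knots: Sequence[Tuple[float, float]], period: float):
        ts = np.asarray([k[0] for k in knots], dtype=float)
        vs = np.asarray([k[1] for k in knots], dtype=float)
        if ts[0] != 0.0 or ts[-1] != 1.0:
            raise ValueError("knots must span fractions 0.0 .. 1.0")
        if abs(vs[0] - vs[-1]) > 1e-12 * max(1.0, abs(vs[0])):
            raise ValueError("waveform must be periodic (v(0) == v(1))")
        if np.any(np.diff(ts) <= 0):
            raise ValueError("knot fractions must be strictly increasing")
        self._ts, self._vs = ts, vs
        self.period = float(period)

    def __call__(self, t):
        """Volume at time ``t`` (seconds, wrapped periodically)."""
        frac = np.mod(np.asarray(t, dtype=float) / self.period, 1.0)
        idx = np.clip(np.searchsorted(self._ts, frac, side="right") - 1, 0,
                      len(self._ts) - 2)
        t0, t1 = self._ts[idx], self._ts[idx + 1]
        v0, v1 = self._vs[idx], self._vs[idx + 1]
        s = (frac - t0) / (t1 - t0)
        return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * s))

    def derivative(self, t):
        """dV/dt at time ``t`` (volume units per second)."""
        frac = np.mod(np.asarray(t, dtype=float) / self.period, 1.0)
        idx = np.clip(np.searchsorted(self._ts, frac, side="right") - 1, 0,
                      len(self._ts) - 2)
        t0, t1 = self._ts[idx], self._ts[idx + 1]
        v0, v1 = self._vs[idx], self._vs[idx + 1]
        s = (frac - t0) / (t1 - t0)
        return (v1 - v0) * 0.5 * np.pi * np.sin(np.pi * s) / ((t1 - t0) * self.period)


def lv_volume_curve(edv: float, esv: float, period: float,
                    timing: CycleTiming = CycleTiming()) -> VolumeCurve:
    """LV waveform: ejection, early filling, diastasis, atrial kick."""
    sv = edv - esv
    tm = timing
    return VolumeCurve(
        [
            (0.0, edv),
            (tm.systole_end, esv),
            (tm.diastasis_start, esv + tm.passive_fraction * sv),
            (tm.atrial_kick_start, esv + tm.passive_fraction * sv),
            (1.0, edv),
        ],
        period,
    )


def la_volume_curve(vmax: float, ef: float, period: float,
                    timing: CycleTiming = CycleTiming()) -> VolumeCurve:
    """LA (or LAA) waveform: reservoir filling during ventricular systole,
    passive conduit emptying, diastasis, then active (booster) emptying
    back to the minimum at end diastole (phase 0)."""
    vmin = vmax * (1.0 - ef)
    tm = timing
    v_mid = vmax - tm.passive_fraction * (vmax - vmin)
    return VolumeCurve(
        [
            (0.0, vmin),
            (tm.systole_end, vmax),
            (tm.diastasis_start, v_mid),
            (tm.atrial_kick_start, v_mid),
            (1.0, vmin),
        ],
        period,
    )


# ---------------------------------------------------------------------------
# polyline helpers (shared with other modules)


def polygon_area(points: np.ndarray) -> float:
    """Signed (shoelace) area of a closed polyline; positive if CCW."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def resample_polyline(points: np.ndarray, spacing: float,
                      closed: bool = False) -> np.ndarray:
    """Resample a polyline at roughly uniform ``spacing``, keeping both
    endpoints (for open lines) or all of the original arclength (closed)."""
    pts = np.asarray(points, dtype=float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(round(total / spacing)), 1)
    snew = np.linspace(0.0, total, n + 1)
    if closed:
        snew = snew[:-1]
    x = np.interp(snew, s, pts[:, 0])
    y = np.interp(snew, s, pts[:, 1])
    return np.column_stack([x, y])


def _clip_area_beyond_line(poly_pts: np.ndarray, point: np.ndarray,
                           normal: np.ndarray) -> float:
    """Area of the part of a closed polyline with ``normal . (x-point) > 0``."""
    poly = Polygon(poly_pts)
    d = poly_pts - point[None, :]
    s = d @ normal
    if np.all(s <= 0):
        return 0.0
    # half plane as a large box on the positive side
    tangent = np.array([-normal[1], normal[0]])
    big = 1e4
    box = Polygon(
        [
            point + tangent * big,
            point - tangent * big,
            point - tangent * big + normal * big,
            point + tangent * big + normal * big,
        ]
    )
    return poly.intersection(box).area


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


# ---------------------------------------------------------------------------
# surface series container


@dataclass
class PhaseLoop:
    """A closed boundary loop with per-phase vertex positions.

    ``vertices`` has shape (phases, n, 2); connectivity is implicit
    (vertex j -> j+1, wrapping), identical at every phase, so vertex
    correspondence across phases holds by construction.
    """

    vertices: np.ndarray
    edge_labels: np.ndarray  # (n,) strings; edge j = (v_j, v_{j+1})

    def polyline(self, phase: int) -> np.ndarray:
        return self.vertices[phase]

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[1]


@dataclass
class SurfaceSeries:
    """Closed chamber boundaries over one cardiac cycle.

    Two loops are stored: ``"la"`` (atrium + appendage, capped by the
    mitral chord and the pulmonary-vein inlets) and ``"lv"`` (ventricle,
    capped by the same mitral chord and the aortic opening).  The mitral
    edges of both loops sample the identical chord so the chambers share
    the valve plane exactly.  ``valve_points`` are interior points along
    the mitral chord used by the flow stage for facet-level valve
    switching.  ``depth`` is the out-of-plane extrusion depth converting
    cross-section areas (mm²) to volumes (mm³).
    """

    loops: Dict[str, PhaseLoop]
    phase_fractions: np.ndarray
    rr_interval: float
    depth: float
    valve_points: np.ndarray  # (phases, n_valve, 2)
    ostium_points: np.ndarray  # (phases, 2) point on the ostium plane
    ostium_normal: np.ndarray  # (2,) unit normal pointing into the LAA
    dimension: int = 2
    spec: Optional[ChamberSpec] = None
    volume_curves: Dict[str, VolumeCurve] = field(default_factory=dict)

    @property
    def phase_count(self) -> int:
        return len(self.phase_fractions)

    def polyline(self, component: str, phase: int) -> np.ndarray:
        return self.loops[component].polyline(phase)

    def volume(self, component: str, phase: int) -> float:
        """Chamber volume (ml) at a phase; the LA loop includes the LAA."""
        area = polygon_area(self.polyline(component, phase))
        return area * self.depth / 1000.0

    def laa_volume(self, phase: int) -> float:
        """Appendage volume (ml): LA-loop area beyond the ostium plane."""
        area = _clip_area_beyond_line(
            self.polyline("la", phase),
            self.ostium_points[phase],
            self.ostium_normal,
        )
        return area * self.depth / 1000.0

    def volume_curve(self, component: str) -> np.ndarray:
        return np.array(
            [self.volume(component, k) for k in range(self.phase_count)]
        )

    def ostium_plane(self, phase: int):
        from .descriptors import OstiumPlane

        return OstiumPlane(
            point=self.ostium_points[phase].copy(),
            normal=self.ostium_normal.copy(),
        )

    def to_trimesh(self, component: str, phase: int):
        """Extruded (prismatic) 3D surface mesh of a chamber cross-section;
        the coarse 3D mode."""
        import trimesh

        from .meshing import triangulate_polygon

        poly = self.polyline(component, phase)
        pts, tris = triangulate_polygon(poly)
        n = len(pts)
        bottom = np.column_stack([pts, np.zeros(n)])
        top = np.column_stack([pts, np.full(n, self.depth)])
        vertices = np.vstack([bottom, top])
        faces = [tris[:, ::-1], tris + n]  # bottom flipped to face down
        # side faces between consecutive boundary vertices
        nb = len(poly)
        idx = np.arange(nb)
        nxt = (idx + 1) % nb
        faces.append(np.column_stack([idx, nxt, nxt + n]))
        faces.append(np.column_stack([idx, nxt + n, idx + n]))
        mesh = trimesh.Trimesh(vertices=vertices,
                               faces=np.vstack(faces), process=False)
        return mesh

    def check_invariants(self) -> None:
        labels = set()
        for name, loop in self.loops.items():
            for k in range(self.phase_count):
                if polygon_area(loop.polyline(k)) <= 0:
                    raise ValueError(
                        f"loop {name!r} phase {k}: boundary not CCW-oriented"
                    )
            labels.update(loop.edge_labels.tolist())
        if "mitral" not in labels or "aortic" not in labels:
            raise ValueError("series must carry mitral and aortic openings")
        if not any(lab.startswith("pv_inlet") for lab in labels):
            raise ValueError("series must carry at least one pv_inlet opening")


# ---------------------------------------------------------------------------
# reference geometry construction


@dataclass
class _GeometryLayout:
    """Internal knobs of the idealized cross-section (all mm)."""

    mitral_half_width: float = 12.0
    pv_width: float = 8.0
    pv_angles: Tuple[float, float] = (70.0, 110.0)  # degrees, from LA centre
    laa_angle: float = 168.0  # degrees; upper-left attachment
    neck_width: float = 4.0
    neck_length: float = 5.0
    aortic_width: float = 9.0
    lv_semi_axis_x: float = 28.0
    blend_halfwidth: float = 8.0  # mm, mitral-plane scale blending band
    sample_spacing: float = 1.0  # mm along boundaries
    depth: float = 40.0  # out-of-plane extrusion depth


def _halfplane(point, normal, big=1e4) -> Polygon:
    """Polygon covering ``normal . (x - point) <= 0``."""
    point = np.asarray(point, float)
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    tangent = np.array([-normal[1], normal[0]])
    return Polygon(
        [
            point + tangent * big,
            point - tangent * big,
            point - tangent * big - normal * big,
            point + tangent * big - normal * big,
        ]
    )


def _circle(center, radius, n=256) -> Polygon:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([center[0] + radius * np.cos(th),
                                    center[1] + radius * np.sin(th)]))


class _ReferenceGeometry:
    """Reference (phase-0, end-diastolic) cross-section and its motion map."""

    def __init__(self, spec: ChamberSpec, layout: _GeometryLayout):
        self.spec = spec
        self.lay = layout
        depth = layout.depth
        # target areas (mm^2) at phase 0: LA at minimum, LV at EDV
        self.area_la_min = spec.la_max_volume * (1 - spec.la_ef) * 1000 / depth
        self.area_laa_min = spec.laa_max_volume * (1 - spec.laa_ef) * 1000 / depth
        self.area_lv_edv = spec.lv_edv * 1000 / depth
        self._build()

    # -- construction -------------------------------------------------
    def _build(self) -> None:
        lay = self.lay
        self.laa_normal = np.array(
            [np.cos(np.radians(lay.laa_angle)), np.sin(np.radians(lay.laa_angle))]
        )
        # pouch radius from appendage minimum area (independent of R_body);
        # small appendages get a proportionally narrower/shorter neck so
        # the pouch always dominates the appendage area
        neck_area = lay.neck_width * lay.neck_length
        if self.area_laa_min < 3.0 * neck_area:
            s = np.sqrt(max(self.area_laa_min / (3.0 * neck_area), 1e-3))
            self.lay = lay = dataclasses.replace(
                lay, neck_width=lay.neck_width * s, neck_length=lay.neck_length * s
            )
        self.pouch_radius = brentq(
            lambda r: self._laa_area_for(r) - self.area_laa_min, 0.2, 60.0,
            xtol=1e-6,
        )
        # LA body radius from total atrial minimum area
        self.body_radius = brentq(
            lambda R: self._la_area_for(R) - self.area_la_min,
            lay.mitral_half_width * 1.05, 200.0, xtol=1e-6,
        )
        # LV ellipse semi-axis b from end-diastolic area
        self.lv_b = brentq(
            lambda b: self._lv_area_for(b) - self.area_lv_edv, 5.0, 400.0,
            xtol=1e-6,
        )
        self._assemble_loops()

    def _la_polygon(self, R: float) -> Tuple[Polygon, np.ndarray]:
        """LA polygon (body + appendage, capped) for body radius R."""
        lay = self.lay
        w = lay.mitral_half_width
        yc = np.sqrt(R * R - w * w)  # centre height so chord at y=0 is ±w
        center = np.array([0.0, yc])
        body = _circle(center, R, n=512)
        n_hat = self.laa_normal
        attach = center + R * n_hat
        t_hat = np.array([-n_hat[1], n_hat[0]])
        hw = lay.neck_width / 2
        neck = Polygon(
            [
                attach - 3 * n_hat + hw * t_hat,
                attach - 3 * n_hat - hw * t_hat,
                attach + lay.neck_length * n_hat - hw * t_hat,
                attach + lay.neck_length * n_hat + hw * t_hat,
            ]
        )
        rp = self.pouch_radius
        pouch = _circle(attach + (lay.neck_length + 0.85 * rp) * n_hat, rp, n=256)
        poly = body.union(neck).union(pouch)
        # mitral cap: keep y >= 0
        poly = poly.intersection(_halfplane((0, 0), (0, -1.0)))
        # pulmonary-vein caps
        for ang in lay.pv_angles:
            nv = np.array([np.cos(np.radians(ang)), np.sin(np.radians(ang))])
            d = np.sqrt(max(R * R - (lay.pv_width / 2) ** 2, 1e-6))
            poly = poly.intersection(_halfplane(center + d * nv, nv))
        return poly, attach

    def _laa_area_for(self, rp: float) -> float:
        self.pouch_radius = rp
        lay = self.lay
        R0 = max(lay.mitral_half_width * 1.5, 18.0)
        poly, attach = self._la_polygon(R0)
        return _clip_area_beyond_line(
            np.asarray(poly.exterior.coords[:-1]), attach, self.laa_normal
        )

    def _la_area_for(self, R: float) -> float:
        poly, _ = self._la_polygon(R)
        return poly.area

    def _lv_polygon(self, b: float) -> Polygon:
        lay = self.lay
        a = lay.lv_semi_axis_x
        w = lay.mitral_half_width
        ratio = np.sqrt(1.0 - (w / a) ** 2)  # e_c / b so chord at y=0 is ±w
        ec = ratio * b
        th = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        ell = Polygon(
            np.column_stack([a * np.cos(th), -ec + b * np.sin(th)])
        )
        poly = ell.intersection(_halfplane((0, 0), (0, 1.0)))
        # aortic opening: vertical cut at the right equator of the ellipse,
        # safely below the valve plane so it cannot touch the mitral chord
        n_a = np.array([1.0, 0.0])
        half_w = lay.aortic_width / 2
        x_cut = a * np.sqrt(max(1.0 - (half_w / b) ** 2, 0.0))
        self._aortic_cut = (np.array([x_cut, -ec]), n_a)
        return poly.intersection(_halfplane(*self._aortic_cut))

    def _lv_area_for(self, b: float) -> float:
        return self._lv_polygon(b).area

    # -- loop sampling and labelling ----------------------------------
    def _assemble_loops(self) -> None:
        lay = self.lay
        la_poly, attach = self._la_polygon(self.body_radius)
        lv_poly = self._lv_polygon(self.lv_b)
        self.ostium_point = attach
        w = lay.mitral_half_width
        yc = np.sqrt(self.body_radius**2 - w * w)
        self._la_center = np.array([0.0, yc])

        n_m = max(int(round(2 * w / lay.sample_spacing)), 4)
        self.mitral_points = np.column_stack(
            [np.linspace(-w, w, n_m + 1), np.zeros(n_m + 1)]
        )

        self.la_vertices, self.la_labels = self._sample_loop(la_poly, chamber="la")
        self.lv_vertices, self.lv_labels = self._sample_loop(lv_poly, chamber="lv")

    def _classify_edge(self, p: np.ndarray, q: np.ndarray, chamber: str) -> str:
        """Label one ring edge.  Cap labels (mitral, pv, aortic) require
        both endpoints to lie on the corresponding cut line, so the caps
        end exactly at the clip corners."""
        lay = self.lay
        tol = 1e-4

        def on_line(point, normal):
            return (
                abs((p - point) @ normal) < tol
                and abs((q - point) @ normal) < tol
            )

        if on_line(np.zeros(2), np.array([0.0, 1.0])):
            return "mitral"
        if chamber == "lv":
            if on_line(*self._aortic_cut):
                return "aortic"
            return "lv"
        R = self.body_radius
        center = self._la_center
        for i, ang in enumerate(lay.pv_angles):
            nv = np.array([np.cos(np.radians(ang)), np.sin(np.radians(ang))])
            d = np.sqrt(max(R * R - (lay.pv_width / 2) ** 2, 1e-6))
            if on_line(center + d * nv, nv):
                return f"pv_inlet_{i + 1}"
        mid = 0.5 * (p + q)
        if (mid - self.ostium_point) @ self.laa_normal > 0:
            return "laa"
        return "la_body"

    def _sample_loop(self, poly: Polygon, chamber: str):
        """Resample a polygon ring at the target spacing, splitting it into
        labelled runs so cap endpoints are preserved exactly, and splicing
        in the shared mitral chord samples."""
        ring = np.asarray(poly.exterior.coords[:-1])
        if polygon_area(ring) < 0:
            ring = ring[::-1]
        # snap the clip corners onto the exact commissure points so both
        # chamber loops share the mitral chord to machine precision
        w = self.lay.mitral_half_width
        for sign in (1.0, -1.0):
            corner = np.array([sign * w, 0.0])
            d = np.linalg.norm(ring - corner, axis=1)
            i = int(np.argmin(d))
            if d[i] < 0.05:
                ring[i] = corner
        nxt = np.roll(ring, -1, axis=0)
        labels = np.array(
            [
                self._classify_edge(ring[i], nxt[i], chamber)
                for i in range(len(ring))
            ]
        )
        # rotate so the ring starts at a label change
        change = np.nonzero(labels != np.roll(labels, 1))[0]
        if len(change):
            k = change[0]
            ring = np.roll(ring, -k, axis=0)
            labels = np.roll(labels, -k)
        verts_out: List[np.ndarray] = []
        labels_out: List[str] = []
        i = 0
        n = len(ring)
        while i < n:
            j = i
            while j < n and labels[j] == labels[i]:
                j += 1
            run_pts = ring[i : j + 1] if j < n else np.vstack([ring[i:], ring[:1]])
            lab = labels[i]
            if lab == "mitral":
                mpts = self.mitral_points
                # orient the shared chord to match the traversal direction
                if run_pts[0, 0] > run_pts[-1, 0]:
                    mpts = mpts[::-1]
                res = mpts
            else:
                res = resample_polyline(run_pts, self.lay.sample_spacing)
            verts_out.append(res[:-1])
            labels_out.extend([lab] * (len(res) - 1))
            i = j
        return np.vstack(verts_out), np.array(labels_out)

    # -- motion map ----------------------------------------------------
    def transform(self, pts: np.ndarray, lam_b: float, lam_lv: float,
                  mu: float) -> np.ndarray:
        """Deform points: radial scaling about the mitral centre with the
        LA factor ``lam_b`` above the valve plane and the LV factor
        ``lam_lv`` below (smoothly blended across it), then an extra
        scaling ``mu`` of the appendage about its (moved) ostium."""
        lay = self.lay
        beta = _smoothstep((pts[:, 1] / lay.blend_halfwidth + 1.0) / 2.0)
        g = beta * lam_b + (1.0 - beta) * lam_lv
        out = pts * g[:, None]
        # appendage: blend in the extra pouch scaling along the neck axis;
        # the half-space beyond the ostium is restricted to the atrial
        # side of the mitral plane so it can never touch the ventricle
        s = (pts - self.ostium_point) @ self.laa_normal
        gamma = _smoothstep(s / lay.neck_length)
        mask = (gamma > 0) & (pts[:, 1] > 0)
        if np.any(mask):
            o = self.ostium_point * (
                _smoothstep((self.ostium_point[1] / lay.blend_halfwidth + 1) / 2)
                * lam_b
                + (1 - _smoothstep((self.ostium_point[1] / lay.blend_halfwidth + 1) / 2))
                * lam_lv
            )
            factor = 1.0 + gamma[mask] * (mu - 1.0)
            out[mask] = o + factor[:, None] * (out[mask] - o)
        return out


# ---------------------------------------------------------------------------
# series generation


def generate_chamber_series(
    spec: ChamberSpec,
    layout: Optional[_GeometryLayout] = None,
    timing: CycleTiming = CycleTiming(),
) -> SurfaceSeries:
    """Build a :class:`SurfaceSeries` matching a :class:`ChamberSpec`.

    Per-phase scale factors (atrial, ventricular, and appendage-pouch) are
    solved with a Newton-type root finder so the LA (including LAA), LAA
    and LV areas hit the prescribed waveform values; EFs therefore round-
    trip through the descriptor layer to well within 1%.  The mapping is
    deterministic — no randomness is involved — so repeated calls return
    bit-identical vertex arrays.
    """
    spec.validate()
    lay = layout or _GeometryLayout()
    ref = _ReferenceGeometry(spec, lay)
    T = spec.rr_interval
    depth = lay.depth

    curves = {
        "lv": lv_volume_curve(spec.lv_edv, spec.lv_esv, T, timing),
        "la": la_volume_curve(spec.la_max_volume, spec.la_ef, T, timing),
        "laa": la_volume_curve(spec.laa_max_volume, spec.laa_ef, T, timing),
    }

    P = spec.phase_count
    fractions = np.arange(P) / P
    all_ref = np.vstack([ref.la_vertices, ref.lv_vertices, ref.mitral_points])
    n_la, n_lv = len(ref.la_vertices), len(ref.lv_vertices)

    la_series = np.empty((P, n_la, 2))
    lv_series = np.empty((P, n_lv, 2))
    valve_series = np.empty((P, len(ref.mitral_points), 2))
    ostium_series = np.empty((P, 2))

    def areas_for(params, t):
        lam_b, lam_lv, mu = params
        pts = ref.transform(all_ref, lam_b, lam_lv, mu)
        la = pts[:n_la]
        lv = pts[n_la : n_la + n_lv]
        o_pt = ref.transform(ref.ostium_point[None, :], lam_b, lam_lv, mu)[0]
        a_la = polygon_area(la)
        a_lv = polygon_area(lv)
        a_laa = _clip_area_beyond_line(la, o_pt, ref.laa_normal)
        return np.array([a_la, a_lv, a_laa]), pts, o_pt

    guess = np.array([1.0, 1.0, 1.0])
    for k in range(P):
        t = fractions[k] * T
        target = np.array(
            [
                curves["la"](t) * 1000 / depth,
                curves["lv"](t) * 1000 / depth,
                curves["laa"](t) * 1000 / depth,
            ]
        )

        def residual(p):
            a, _, _ = areas_for(p, t)
            return a - target

        sol = root(residual, guess, method="hybr", tol=1e-10)
        if not sol.success or np.max(np.abs(sol.fun) / target) > 5e-3:
            raise RuntimeError(
                f"phase {k}: could not match target chamber areas "
                f"(residual {sol.fun})"
            )
        params = sol.x
        guess = params
        _, pts, o_pt = areas_for(params, t)
        la_series[k] = pts[:n_la]
        lv_series[k] = pts[n_la : n_la + n_lv]
        valve_series[k] = pts[n_la + n_lv :]
        ostium_series[k] = o_pt

    series = SurfaceSeries(
        loops={
            "la": PhaseLoop(la_series, ref.la_labels),
            "lv": PhaseLoop(lv_series, ref.lv_labels),
        },
        phase_fractions=fractions,
        rr_interval=T,
        depth=depth,
        valve_points=valve_series,
        ostium_points=ostium_series,
        ostium_normal=ref.laa_normal.copy(),
        dimension=spec.dimension,
        spec=dataclasses.replace(spec),
        volume_curves=curves,
    )
    series.check_invariants()
    return series


# ---------------------------------------------------------------------------
# cohorts


def generate_cohort(cohort: CohortSpec):
    """Draw a two-group cohort of :class:`ChamberSpec`.

    Returns a list of ``(subject_id, ChamberSpec, group_label)``; group
    labels are ``"control"`` and ``"af"``.  Parameters are drawn from
    independent normals; invalid draws are rejected and redrawn up to
    ``cohort.max_redraws`` times.  Identical seeds give identical cohorts.
    """
    cohort.validate()
    rng = np.random.default_rng(cohort.seed)
    out = []
    plan = [("control", cohort.n_control), ("af", cohort.n_af)]
    counter = 0
    for group, n in plan:
        dists = cohort.parameter_distributions[group]
        p_cw = cohort.cw_probability.get(group, 1.0)
        for _ in range(n):
            spec = None
            for _attempt in range(cohort.max_redraws + 1):
                draw = {
                    name: rng.normal(mean, sd) for name, (mean, sd) in dists.items()
                }
                shape = (
                    "chicken_wing"
                    if rng.uniform() < p_cw
                    else "non_chicken_wing"
                )
                candidate = ChamberSpec(
                    la_max_volume=draw["la_max_volume_idx"] * draw["bsa"],
                    la_ef=draw["la_ef"],
                    laa_max_volume=draw["laa_max_volume_idx"] * draw["bsa"],
                    laa_ef=draw["laa_ef"],
                    lv_edv=draw["lv_edv_idx"] * draw["bsa"],
                    lv_esv=draw["lv_esv_idx"] * draw["bsa"],
                    heart_rate=draw["heart_rate"],
                    bsa=draw["bsa"],
                    laa_shape_label=shape,
                )
                try:
                    candidate.validate()
                except ValueError:
                    continue
                spec = candidate
                break
            if spec is None:
                raise RuntimeError(
                    f"could not draw a valid {group} subject within "
                    f"{cohort.max_redraws} redraws; check the distributions"
                )
            counter += 1
            out.append((f"{group}_{counter:03d}", spec, group))
    return out


# ---------------------------------------------------------------------------
# voxelization


@dataclass
class MaskStack:
    """Per-phase binary masks of one chamber cross-section.

    2D masks with pixel-centred, 0-based indexing: pixel (i, j) covers the
    point ``origin + (j + 0.5, i + 0.5) * spacing`` — row index is y.
    """

    masks: np.ndarray  # (phases, ny, nx) bool
    origin: np.ndarray  # (2,) mm, lower-left corner of pixel (0, 0)
    spacing: float  # mm
    depth: float  # mm

    def volume(self, phase: int) -> float:
        """Mask volume in ml (pixel count × pixel area × depth)."""
        return (
            float(np.count_nonzero(self.masks[phase]))
            * self.spacing**2
            * self.depth
            / 1000.0
        )

    def contour(self, phase: int) -> np.ndarray:
        """Longest iso-contour of the mask in mm coordinates."""
        from skimage import measure

        contours = measure.find_contours(
            self.masks[phase].astype(float), 0.5
        )
        if not contours:
            raise ValueError(f"phase {phase}: empty mask has no contour")
        c = max(contours, key=len)  # (row=y, col=x) in index space
        xy = np.column_stack([c[:, 1], c[:, 0]])
        return self.origin[None, :] + (xy + 0.0) * self.spacing + 0.5 * self.spacing


def voxelize(series: SurfaceSeries, voxel_size: float,
             component: str = "la", margin: float = 2.0) -> MaskStack:
    """Rasterize one chamber loop of every phase to binary masks.

    The grid is shared across phases (fixed origin/spacing) so masks are
    directly comparable; a pixel is inside if its centre falls within the
    phase polygon.  Raises if ``voxel_size`` is non-positive or too coarse
    to produce a non-empty mask.
    """
    if not voxel_size > 0:
        raise ValueError(f"voxel_size must be > 0, got {voxel_size}")
    polys = [series.polyline(component, k) for k in range(series.phase_count)]
    allpts = np.vstack(polys)
    lo = allpts.min(axis=0) - margin
    hi = allpts.max(axis=0) + margin
    nx = int(np.ceil((hi[0] - lo[0]) / voxel_size))
    ny = int(np.ceil((hi[1] - lo[1]) / voxel_size))
    xs = lo[0] + (np.arange(nx) + 0.5) * voxel_size
    ys = lo[1] + (np.arange(ny) + 0.5) * voxel_size
    X, Y = np.meshgrid(xs, ys)
    masks = np.empty((series.phase_count, ny, nx), dtype=bool)
    for k, poly in enumerate(polys):
        inside = shapely.contains_xy(Polygon(poly), X.ravel(), Y.ravel())
        masks[k] = inside.reshape(ny, nx)
        if not masks[k].any():
            raise ValueError(
                f"voxel_size {voxel_size} mm too coarse: empty mask at phase {k}"
            )
    return MaskStack(masks=masks, origin=lo, spacing=voxel_size,
                     depth=series.depth)
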