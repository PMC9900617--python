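"""Aneurysm morphometry from a parametric vessel model.

The vessel is represented by a centerline polyline with per-station lumen and
outer radii — the reduced form of what clinical segmentation tools export.
All of the cohort study's geometric variables derive from it:

- maximum (outer and lumen) diameter, perpendicular to the centerline;
- maximum intraluminal-thrombus (ILT) thickness, defined radially per station
  as outer minus lumen radius;
- neck angulation: suprarenal→infrarenal-neck angle (alpha) and neck→aneurysm
  angle (beta), from mean unit tangents over fixed-arclength windows;
- neck length and diameter (lowest renal artery to start of aneurysm);
- aortic and iliac tortuosity indices (centerline arclength / straight-line
  "raceline" distance between anatomical stations);
- lumen, total vessel and ILT volumes by conical-frustum integration, with
  ILT = vessel - lumen exact by construction.

Stations are named indices into the polyline: ``lowest_renal`` (P2),
``aortic_bifurcation`` (P4), ``inguinal_ligament`` (P8), ``neck_end`` and
``aaa_start``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

logger = logging.getLogger(__name__)

#: Arclength window (mm) over which tangents are averaged for the neck angles.
DEFAULT_ANGLE_WINDOW_MM = 15.0

STATION_ORDER = ("lowest_renal", "neck_end", "aaa_start", "aortic_bifurcation", "inguinal_ligament")


@dataclass(frozen=True)
class Centerline:
    """Ordered 3-D polyline (mm) with named anatomical stations."""

    points: np.ndarray  # (n, 3)
    stations: dict = field(default_factory=dict)  # label -> index

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ValueError("centerline needs >= 2 points of shape (n, 3)")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive centerline points must be distinct")
        for lab, idx in self.stations.items():
            if not 0 <= idx < len(pts):
                raise ValueError(f"station {lab!r} index {idx} out of range")
        order = [self.stations[s] for s in ("lowest_renal", "aortic_bifurcation", "inguinal_ligament") if s in self.stations]
        if order != sorted(order):
            raise ValueError("stations out of anatomical order (renal -> bifurcation -> inguinal)")
        object.__setattr__(self, "points", pts)

    @property
    def arclength(self) -> np.ndarray:
        """Cumulative arclength (mm), 0 at the first point."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def station_index(self, label: str) -> int:
        if label not in self.stations:
            raise KeyError(f"station {label!r} not defined on this centerline")
        return self.stations[label]


@dataclass(frozen=True)
class VesselModel:
    """Centerline plus per-station lumen and outer-contour radii (mm)."""

    centerline: Centerline
    lumen_radius: np.ndarray  # (n,)
    outer_radius: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        n = len(self.centerline.points)
        lum = np.asarray(self.lumen_radius, float)
        out = np.asarray(self.outer_radius, float)
        if lum.shape != (n,) or out.shape != (n,):
            raise ValueError("radius profiles must match the centerline length")
        if np.any(lum < 0) or np.any(out < lum - 1e-12):
            raise ValueError("need outer_radius >= lumen_radius >= 0 at every station")
        object.__setattr__(self, "lumen_radius", lum)
        object.__setattr__(self, "outer_radius", np.maximum(out, lum))

    @property
    def ilt_thickness(self) -> np.ndarray:
        """Radial ILT thickness per station: outer minus lumen radius (mm)."""
        return self.outer_radius - self.lumen_radius


@dataclass(frozen=True)
class GeometricMetrics:
    """The morphometric variable set tracked per patient-timepoint."""

    max_diameter: float  # mm, outer contour
    max_diameter_index: int
    max_lumen_diameter: float  # mm
    max_ilt_thickness: float  # mm
    max_ilt_index: int
    alpha_angle: float  # degrees
    beta_angle: float  # degrees
    neck_length: float  # mm
    neck_diameter: float  # mm
    aortic_tortuosity: float
    iliac_tortuosity: float | None  # None when no iliac branch supplied
    lumen_volume: float  # mm^3
    vessel_volume: float  # mm^3
    ilt_volume: float  # mm^3


def tortuosity_index(c: Centerline, from_station: str, to_station: str) -> float:
    """Centerline-to-raceline ratio between two stations (>= 1 for a polyline)."""
    i, j = c.station_index(from_station), c.station_index(to_station)
    if i >= j:
        raise ValueError(f"station {from_station!r} must precede {to_station!r}")
    arc = c.arclength
    along = float(arc[j] - arc[i])
    chord = float(np.linalg.norm(c.points[j] - c.points[i]))
    if chord == 0:
        raise ValueError(
            f"stations {from_station!r} and {to_station!r} coincide: raceline distance 0"
        )
    return along / chord


def max_diameter(m: VesselModel, use: Literal["lumen", "outer"] = "outer") -> tuple[float, int]:
    """Maximum diameter (2 x max radius) of the chosen profile and its station.

    Ties go to the proximal (smallest-index) station and are logged.
    """
    r = m.lumen_radius if use == "lumen" else m.outer_radius
    idx = int(np.argmax(r))  # argmax returns the first (proximal) maximum
    if np.sum(r == r[idx]) > 1:
        logger.info("max_diameter: tie at %.3f mm broken toward proximal station %d", 2 * r[idx], idx)
    return float(2.0 * r[idx]), idx


def max_ilt_thickness(m: VesselModel) -> tuple[float, int]:
    """Maximum radial ILT thickness (mm) and its station index (ties proximal)."""
    th = m.ilt_thickness
    idx = int(np.argmax(th))
    if np.sum(th == th[idx]) > 1:
        logger.info("max_ilt_thickness: tie at %.3f mm broken toward proximal station %d", th[idx], idx)
    return float(th[idx]), idx


def _mean_tangent(c: Centerline, start: int, stop: int) -> np.ndarray:
    """Mean unit tangent of the polyline slice [start, stop] (>= 2 points)."""
    pts = c.points[start : stop + 1]
    if len(pts) < 2:
        raise ValueError(f"segment [{start}, {stop}] has fewer than 2 points")
    d = np.diff(pts, axis=0)
    t = d / np.linalg.norm(d, axis=1, keepdims=True)
    mt = t.mean(axis=0)
    nrm = np.linalg.norm(mt)
    if nrm == 0:
        raise ValueError(f"segment [{start}, {stop}] has vanishing mean tangent")
    return mt / nrm


def _window_before(c: Centerline, idx: int, window_mm: float) -> int:
    """Index where an arclength window of `window_mm` ending at idx starts."""
    arc = c.arclength
    j = int(np.searchsorted(arc, arc[idx] - window_mm, side="left"))
    return min(j, idx - 1)


def _window_after(c: Centerline, idx: int, window_mm: float) -> int:
    arc = c.arclength
    j = int(np.searchsorted(arc, arc[idx] + window_mm, side="right")) - 1
    return max(j, idx + 1)


def neck_angles(c: Centerline, window_mm: float = DEFAULT_ANGLE_WINDOW_MM) -> tuple[float, float]:
    """Suprarenal→neck (alpha) and neck→aneurysm (beta) angulation in degrees.

    Each angle is measured between mean unit tangents averaged over
    ``window_mm`` of arclength on either side of the junction: alpha at the
    lowest renal artery, beta at the start of the aneurysm. Values lie in
    [0, 180).
    """
    i_renal = c.station_index("lowest_renal")
    i_neck_end = c.station_index("neck_end")
    i_aaa = c.station_index("aaa_start")
    if i_renal < 1:
        raise ValueError("no suprarenal segment: lowest_renal is the first point")
    supra = _mean_tangent(c, _window_before(c, i_renal, window_mm), i_renal)
    neck_stop = max(i_renal + 1, min(i_neck_end, _window_after(c, i_renal, window_mm)))
    neck = _mean_tangent(c, i_renal, neck_stop)
    aaa = _mean_tangent(c, i_aaa, _window_after(c, i_aaa, window_mm))

    def _angle(u: np.ndarray, v: np.ndarray) -> float:
        cosang = float(np.clip(np.dot(u, v), -1.0, 1.0))
        ang = float(np.degrees(np.arccos(cosang)))
        return 0.0 if ang < 1e-12 else min(ang, np.nextafter(180.0, 0.0))

    return _angle(supra, neck), _angle(neck, aaa)


def volumes(m: VesselModel) -> tuple[float, float, float]:
    """(lumen, vessel, ILT) volumes in mm^3 by conical-frustum integration.

    Each consecutive station pair contributes pi/3 * h * (r1^2 + r1 r2 + r2^2)
    with h the inter-station arclength. The ILT volume is vessel - lumen, so
    additivity is exact by construction.
    """
    h = np.linalg.norm(np.diff(m.centerline.points, axis=0), axis=1)

    def frustum(r: np.ndarray) -> float:
        r1, r2 = r[:-1], r[1:]
        return float((np.pi / 3.0) * np.sum(h * (r1**2 + r1 * r2 + r2**2)))

    lumen = frustum(m.lumen_radius)
    vessel = frustum(m.outer_radius)
    return lumen, vessel, vessel - lumen


def neck_measures(c: Centerline, m: VesselModel) -> tuple[float, float]:
    """(neck length, neck diameter) in mm.

    Neck length is the arclength from the lowest renal artery to the start of
    the aneurysm; neck diameter is twice the outer radius at the lowest renal
    artery.
    """
    i_renal = c.station_index("lowest_renal")
    i_aaa = c.station_index("aaa_start")
    if i_aaa < i_renal:
        raise ValueError("aaa_start precedes lowest_renal")
    arc = c.arclength
    length = float(arc[i_aaa] - arc[i_renal])
    diameter = float(2.0 * m.outer_radius[i_renal])
    return length, diameter


def compute_geometric_metrics(
    m: VesselModel,
    iliac: Centerline | None = None,
    angle_window_mm: float = DEFAULT_ANGLE_WINDOW_MM,
) -> GeometricMetrics:
    """Assemble the full morphometric variable set for one vessel model.

    The iliac tortuosity needs a separate iliac centerline branch running from
    the aortic bifurcation to the inguinal ligament; when absent it is
    reported as missing (``None``), never imputed.
    """
    c = m.centerline
    dmax, i_dmax = max_diameter(m, "outer")
    dlum, _ = max_diameter(m, "lumen")
    ilt, i_ilt = max_ilt_thickness(m)
    alpha, beta = neck_angles(c, angle_window_mm)
    nlen, ndia = neck_measures(c, m)
    aort = tortuosity_index(c, "lowest_renal", "aortic_bifurcation")
    il = None
    if iliac is not None:
        il = tortuosity_index(iliac, "aortic_bifurcation", "inguinal_ligament")
    lum, ves, iltv = volumes(m)
    return GeometricMetrics(
        max_diameter=dmax,
        max_diameter_index=i_dmax,
        max_lumen_diameter=dlum,
        max_ilt_thickness=ilt,
        max_ilt_index=i_ilt,
        alpha_angle=alpha,
        beta_angle=beta,
        neck_length=nlen,
        neck_diameter=ndia,
        aortic_tortuosity=aort,
        iliac_tortuosity=il,
        lumen_volume=lum,
        vessel_volume=ves,
        ilt_volume=iltv,
    )
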