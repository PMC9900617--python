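"""Analytic wall-stress / wall-strength surrogate.

The cohort analysis tracks peak wall stress (PWS) and the peak wall rupture
index (PWRI, the maximum local stress-to-strength ratio) together with the 3-D
points where they occur. Here both fields are produced by a deliberately
simple, fully documented analytic model over the centerline stations of a
:class:`~aaamotion.geometry.VesselModel`:

stress
    Thin-wall Laplace stress with exponential intraluminal-thrombus (ILT)
    buffering::

        sigma(s) = P * r_outer(s) / (2 * t_wall) * exp(-k * ilt(s))

    with ``P`` the analysis pressure (kPa), ``t_wall`` a constant wall
    thickness and ``k`` an ILT attenuation rate (1/mm). The spherical factor
    ``r/2t`` is used because a fusiform sac at its bulge is closer to a
    spherical cap than to a straight cylinder; the choice only affects scale.

strength
    Linear strength loss under thrombus, clamped at a floor::

        S(s) = max(floor, S0 - c * ilt(s))

The model is deterministic, rigid-motion invariant and linear in pressure, so
the PWS location does not move when pressure changes — mirroring the clinical
observation that maximum-point positions are insensitive to blood pressure.
It generates plausible, controllable maxima for the motion pipeline; it does
not attempt to reproduce values of a nonlinear finite-element analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from aaamotion.geometry import VesselModel

logger = logging.getLogger(__name__)

MMHG_TO_KPA = 0.133322


@dataclass(frozen=True)
class PressureSpec:
    """Arterial pressure for the analysis; the study standard is 140/80 mm Hg.

    The analysis pressure defaults to the mean arterial pressure,
    diastolic + (systolic - diastolic)/3, converted to kPa. Set
    ``use_systolic=True`` to analyse at systole instead.
    """

    systolic: float = 140.0  # mm Hg
    diastolic: float = 80.0  # mm Hg
    use_systolic: bool = False

    def __post_init__(self) -> None:
        if not self.systolic > self.diastolic > 0:
            raise ValueError("need systolic > diastolic > 0")

    @property
    def analysis_pressure(self) -> float:
        """Pressure driving the stress field, kPa."""
        mmhg = (
            self.systolic
            if self.use_systolic
            else self.diastolic + (self.systolic - self.diastolic) / 3.0
        )
        return mmhg * MMHG_TO_KPA


@dataclass(frozen=True)
class SurrogateParams:
    """Tunable constants of the analytic stress/strength model."""

    wall_thickness: float = 2.0  # mm
    ilt_attenuation: float = 0.03  # 1/mm
    base_strength: float = 800.0  # kPa
    ilt_strength_loss: float = 15.0  # kPa/mm
    strength_floor: float = 300.0  # kPa

    def __post_init__(self) -> None:
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be > 0")
        if self.ilt_attenuation < 0:
            raise ValueError("ilt_attenuation must be >= 0")
        if not self.base_strength > self.strength_floor > 0:
            raise ValueError("need base_strength > strength_floor > 0")


@dataclass(frozen=True)
class StressField:
    """Per-station stress, strength and rupture index along the centerline."""

    stress: np.ndarray  # kPa
    strength: np.ndarray  # kPa
    rupture_index: np.ndarray = None  # dimensionless, derived as stress/strength

    def __post_init__(self) -> None:
        s = np.asarray(self.stress, float)
        st = np.asarray(self.strength, float)
        if s.shape != st.shape:
            raise ValueError("stress and strength must have equal length")
        if np.any(s < 0) or np.any(st <= 0):
            raise ValueError("need stress >= 0 and strength > 0")
        object.__setattr__(self, "stress", s)
        object.__setattr__(self, "strength", st)
        object.__setattr__(self, "rupture_index", s / st)


@dataclass(frozen=True)
class BiomechMetrics:
    """PWS and PWRI with their station indices and 3-D locations."""

    pws: float  # kPa
    pws_index: int
    pws_location: np.ndarray  # mm, centerline-surface point
    pwri: float
    pwri_index: int
    pwri_location: np.ndarray
    mean_ilt_stress: float  # kPa; mean stress over stations carrying ILT


def strength_field(m: VesselModel, params: SurrogateParams = SurrogateParams()) -> np.ndarray:
    """Per-station wall strength (kPa): linear ILT loss clamped at the floor."""
    return np.maximum(
        params.strength_floor,
        params.base_strength - params.ilt_strength_loss * m.ilt_thickness,
    )


def stress_field(
    m: VesselModel,
    pressure: PressureSpec = PressureSpec(),
    params: SurrogateParams = SurrogateParams(),
) -> StressField:
    """Laplace wall stress with ILT buffering, plus strength and rupture index."""
    P = pressure.analysis_pressure
    sigma = (
        P
        * m.outer_radius
        / (2.0 * params.wall_thickness)
        * np.exp(-params.ilt_attenuation * m.ilt_thickness)
    )
    return StressField(stress=sigma, strength=strength_field(m, params))


def _surface_point(m: VesselModel, idx: int) -> np.ndarray:
    """A 3-D point on the outer contour at station idx.

    The surface point is the centerline point offset by the outer radius along
    a direction perpendicular to the local tangent (deterministic choice).
    """
    pts = m.centerline.points
    j = min(idx + 1, len(pts) - 1)
    i = j - 1
    t = pts[j] - pts[i]
    t = t / np.linalg.norm(t)
    # any fixed reference not parallel to t
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n = np.cross(t, ref)
    n = n / np.linalg.norm(n)
    return pts[idx] + m.outer_radius[idx] * n


def biomech_metrics(field: StressField, m: VesselModel) -> BiomechMetrics:
    """Extract PWS and PWRI (value, station, 3-D location) from the fields.

    Ties are broken toward the proximal station and logged. The 3-D locations
    are exported as the ``max_pws`` / ``max_pwri`` landmarks fed to the
    registration stage.
    """
    n = len(m.centerline.points)
    if len(field.stress) != n:
        raise ValueError("field length does not match the centerline")
    i_pws = int(np.argmax(field.stress))
    if np.sum(field.stress == field.stress[i_pws]) > 1:
        logger.info("biomech_metrics: PWS tie broken toward proximal station %d", i_pws)
    i_pwri = int(np.argmax(field.rupture_index))
    if np.sum(field.rupture_index == field.rupture_index[i_pwri]) > 1:
        logger.info("biomech_metrics: PWRI tie broken toward proximal station %d", i_pwri)
    with_ilt = m.ilt_thickness > 0
    mean_ilt = float(field.stress[with_ilt].mean()) if np.any(with_ilt) else float("nan")
    return BiomechMetrics(
        pws=float(field.stress[i_pws]),
        pws_index=i_pws,
        pws_location=_surface_point(m, i_pws),
        pwri=float(field.rupture_index[i_pwri]),
        pwri_index=i_pwri,
        pwri_location=_surface_point(m, i_pwri),
        mean_ilt_stress=mean_ilt,
    )
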