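"""Paired-timepoint synthetic AAA cohort generator.

Each synthetic patient consists of:

- a CT1 vessel model: a gently curved centerline with a fusiform lumen bulge
  and a Gaussian intraluminal-thrombus (ILT) crescent, plus an iliac branch
  centerline for the iliac tortuosity;
- a CT2 vessel model grown from CT1: the outer contour of the aneurysm region
  is scaled so that the *drawn* vessel-volume increase is realized exactly
  (the vessel volume is a quadratic polynomial in the scale factor, so the
  scale solves in closed form);
- nine fit landmarks (renal arteries, SMA, aortic bifurcation, iliac and
  lumbar arteries), one held-out validation landmark (IMA-like) and the three
  maximum points (max ILT thickness, PWS, PWRI) taken from the geometry and
  biomechanical-surrogate modules;
- a planted CT1→CT2 linear transformation; CT2 fit/validation landmarks are
  its images plus isotropic Gaussian noise (default sd 1.5 mm, the
  slice-thickness scale of the imaging data the cohort emulates);
- planted max-point motions: each CT2 maximum point is the transformed CT1
  point displaced *tangentially* to the local surface by a drawn magnitude,
  so true motion never aliases into pure growth, and magnitudes are drawn
  independently of every geometric change (the cohort-level null the study
  reports).

Cohort-level change structure
-----------------------------
Per-patient annual change rates of vessel volume, PWS and PWRI are drawn from
a Gaussian copula with lognormal margins. The latent correlations are solved
in closed form so that the *population Pearson correlation of the absolute
deltas* — including the correlation induced by the shared CT interval —
equals the configured targets (defaults 0.68 for Δvolume–ΔPWS and 0.60 for
Δvolume–ΔPWRI). Growth is anchored to the configured annual diameter growth
distribution (default median 3.7 mm/year, IQR 2.25–5.44): the volume-rate
margin is calibrated from the template geometry so the median diameter growth
matches. Record-table PWS/PWRI at CT2 are the CT1 surrogate values plus the
drawn deltas, emulating finite-element outputs that are not a deterministic
function of the reduced centerline model.

Reproducibility: one global seed; each patient derives its own generator from
``(seed, patient_index)`` (splitmix-style stream split via numpy's
``SeedSequence``), so generation is order-independent and parallel-safe.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm as _norm

from aaamotion.biomech import PressureSpec, SurrogateParams, biomech_metrics, stress_field
from aaamotion.geometry import (
    Centerline,
    VesselModel,
    compute_geometric_metrics,
    volumes,
)
from aaamotion.registration import (
    CorrespondenceSet,
    Landmark,
    LinearTransform,
)

_Z75 = float(_norm.ppf(0.75))  # 0.6745…, maps an IQR ratio to a lognormal sigma


@dataclass(frozen=True)
class TransformSpec:
    """Ranges for the planted CT1→CT2 transformation components."""

    family: Literal["rigid", "similarity", "affine"] = "affine"
    rotation_deg: float = 8.0  # max |angle| per axis
    translation_mm: float = 40.0  # max |component|
    scale_range: tuple = (0.98, 1.02)  # similarity/affine
    shear: float = 0.01  # affine only, max |off-diagonal|


@dataclass(frozen=True)
class MotionSpec:
    """Lognormal magnitude distribution of true tangential max-point motion."""

    median_mm: float = 10.0
    sigma: float = 0.8

    def __post_init__(self) -> None:
        if self.median_mm <= 0 or self.sigma <= 0:
            raise ValueError("motion median and sigma must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 32
    seed: int = 0
    interval_min_months: float = 6.0
    interval_max_months: float = 24.0
    growth_median: float = 3.7  # mm/year, annual diameter growth
    growth_q1: float = 2.25
    growth_q3: float = 5.44
    landmark_noise_sd: float = 1.5  # mm, isotropic, fit + validation landmarks
    rho_vol_pws: float = 0.68  # target Pearson, delta vessel volume vs delta PWS
    rho_vol_pwri: float = 0.60
    rho_pws_pwri: float = 0.75
    pws_rate_sigma: float = 0.7  # lognormal sigma of the annual PWS change
    pwri_rate_sigma: float = 0.7
    motion: MotionSpec = MotionSpec()
    transform: TransformSpec = TransformSpec()

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 < self.interval_min_months < self.interval_max_months:
            raise ValueError("need 0 < interval_min < interval_max")
        if not 0 < self.growth_q1 < self.growth_median < self.growth_q3:
            raise ValueError("growth quartiles must bracket the median")
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark_noise_sd must be >= 0")
        for rho in (self.rho_vol_pws, self.rho_vol_pwri, self.rho_pws_pwri):
            if not abs(rho) < 1:
                raise ValueError("correlation targets must satisfy |rho| < 1")


@dataclass
class SyntheticPatient:
    """One simulated paired-timepoint patient with full ground truth."""

    patient_id: str
    interval_months: float
    age_years: float
    ct1_model: VesselModel
    ct2_model: VesselModel
    ct1_iliac: Centerline
    ct2_iliac: Centerline
    ct1_landmarks: list
    ct2_landmarks: list
    transform: LinearTransform  # planted ground truth
    true_motions: dict  # label -> mm
    record: dict  # metric row (CT1/CT2 values, motions, ground truth)

    @property
    def correspondences(self) -> CorrespondenceSet:
        """Pair up CT1/CT2 landmarks by label into a CorrespondenceSet."""
        by1 = {lm.label: lm for lm in self.ct1_landmarks}
        by2 = {lm.label: lm for lm in self.ct2_landmarks}
        fit, val, mp = [], None, []
        for lab, lm in by1.items():
            pair = (lm.position, by2[lab].position, lab)
            if lm.role == "fit":
                fit.append(pair)
            elif lm.role == "validation":
                val = pair
            else:
                mp.append(pair)
        return CorrespondenceSet(self.patient_id, tuple(fit), val, tuple(mp))


# ----------------------------------------------------------------------------
# baseline anatomy


def _gauss(s: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((s - center) / width) ** 2)


def _baseline_params(rng: np.random.Generator | None) -> dict:
    """Anatomical parameters, jittered per patient (rng=None → template)."""

    def d(central: float, spread: float) -> float:
        return central if rng is None else central + spread * float(rng.standard_normal())

    def u(lo: float, hi: float) -> float:
        return 0.5 * (lo + hi) if rng is None else float(rng.uniform(lo, hi))

    return dict(
        r_base=d(11.0, 0.5),  # mm, non-aneurysmal lumen radius
        lum_amp=d(6.5, 0.8),  # mm, lumen bulge amplitude
        ilt_amp=u(8.0, 13.0),  # mm, ILT crescent amplitude
        ilt_shift=u(-8.0, 8.0),  # mm, ILT peak offset from bulge center
        neck_len=u(14.0, 28.0),  # mm
        alpha_bend=u(8.0, 20.0),  # deg, suprarenal→neck bend
        beta_bend=u(15.0, 35.0),  # deg, neck→aneurysm bend
        wiggle_x=d(3.0, 0.5),  # mm, centerline undulation amplitudes
        wiggle_y=d(2.0, 0.4),
        iliac_amp=d(20.0, 2.0),  # mm, iliac branch undulation
    )


_ARC_STEP = 1.0  # mm
_LEN_MAIN = 160.0  # mm, suprarenal aorta to just below bifurcation
_S_RENAL = 30.0
_S_BIF = 150.0
_S_AAA_END = 140.0
_LEN_ILIAC = 60.0


def _main_centerline(p: dict) -> Centerline:
    s = np.arange(0.0, _LEN_MAIN + _ARC_STEP / 2, _ARC_STEP)
    s_aaa = _S_RENAL + p["neck_len"]
    x = p["wiggle_x"] * np.sin(2 * np.pi * s / 240.0)
    y = p["wiggle_y"] * np.sin(2 * np.pi * s / 200.0)
    # angulation: piecewise-linear direction changes at the renal level (alpha)
    # and at the start of the aneurysm (beta)
    x = x + np.tan(np.radians(p["alpha_bend"])) * np.maximum(0.0, s - _S_RENAL)
    y = y + np.tan(np.radians(p["beta_bend"])) * np.maximum(0.0, s - s_aaa)
    pts = np.column_stack([x, y, -s])
    stations = {
        "lowest_renal": int(round(_S_RENAL / _ARC_STEP)),
        "neck_end": int(round(s_aaa / _ARC_STEP)),
        "aaa_start": int(round(s_aaa / _ARC_STEP)),
        "aortic_bifurcation": int(round(_S_BIF / _ARC_STEP)),
    }
    return Centerline(pts, stations)


def _radius_profiles(p: dict, c: Centerline) -> tuple[np.ndarray, np.ndarray]:
    n = len(c.points)
    s = np.arange(n) * _ARC_STEP
    s_aaa = _S_RENAL + p["neck_len"]
    center = 0.5 * (s_aaa + _S_AAA_END)
    width = (_S_AAA_END - s_aaa) / 4.5
    lumen = p["r_base"] + p["lum_amp"] * _gauss(s, center, width)
    ilt = p["ilt_amp"] * _gauss(s, center + p["ilt_shift"], 0.8 * width)
    ilt[ilt < 0.05] = 0.0  # crescent has finite extent
    return lumen, lumen + ilt


def _iliac_centerline(p: dict, origin: np.ndarray, amp: float) -> Centerline:
    s = np.arange(0.0, _LEN_ILIAC + 0.75, 1.5)
    x = amp * np.sin(np.pi * s / _LEN_ILIAC)
    pts = origin + np.column_stack([x, 0.3 * x, -s - 1.0])
    return Centerline(pts, {"aortic_bifurcation": 0, "inguinal_ligament": len(s) - 1})


def _build_ct1(p: dict) -> tuple[VesselModel, Centerline]:
    c = _main_centerline(p)
    lumen, outer = _radius_profiles(p, c)
    model = VesselModel(c, lumen, outer)
    iliac = _iliac_centerline(p, c.points[c.stations["aortic_bifurcation"]], p["iliac_amp"])
    return model, iliac


# ----------------------------------------------------------------------------
# growth: realize a drawn vessel-volume increase exactly


def _aaa_region(c: Centerline) -> np.ndarray:
    i0 = c.stations["aaa_start"]
    i1 = int(round(_S_AAA_END / _ARC_STEP))
    mask = np.zeros(len(c.points), bool)
    mask[i0 : i1 + 1] = True
    return mask


_LUMEN_GROWTH_FRACTION = 0.45  # lumen grows slower than the outer contour


def grow_model(m: VesselModel, delta_vessel_volume: float) -> tuple[VesselModel, float]:
    """Return a grown copy of ``m`` whose vessel volume increased by exactly
    ``delta_vessel_volume`` (mm³), plus the applied outer scale factor.

    Outer radii in the aneurysm region are scaled by ``s``; the frustum vessel
    volume is a quadratic polynomial in ``s``, so ``s`` is the positive root
    closest to 1. The lumen is scaled by ``1 + 0.45 (s - 1)``, so the ILT
    grows faster than the lumen, as observed in growing aneurysms.
    """
    mask = _aaa_region(m.centerline)
    _, v1, _ = volumes(m)
    target = v1 + delta_vessel_volume

    def vessel_at(scale: float) -> float:
        outer = np.where(mask, m.outer_radius * scale, m.outer_radius)
        return volumes(VesselModel(m.centerline, np.minimum(m.lumen_radius, outer), outer))[1]

    v0, v2 = vessel_at(0.0), vessel_at(2.0)
    cc = (v2 - 2 * v1 + v0) / 2.0
    bb = v1 - v0 - cc
    # solve a + b s + c s^2 = target
    disc = bb * bb - 4 * cc * (v0 - target)
    if disc < 0 or cc <= 0:
        raise ValueError("volume target not realizable on this geometry")
    roots = [(-bb + np.sqrt(disc)) / (2 * cc), (-bb - np.sqrt(disc)) / (2 * cc)]
    s = min((r for r in roots if r > 0), key=lambda r: abs(r - 1.0))
    s_lum = 1.0 + _LUMEN_GROWTH_FRACTION * (s - 1.0)
    outer = np.where(mask, m.outer_radius * s, m.outer_radius)
    lumen = np.where(mask, m.lumen_radius * s_lum, m.lumen_radius)
    lumen = np.minimum(lumen, outer)
    return VesselModel(m.centerline, lumen, outer), float(s)


# ----------------------------------------------------------------------------
# copula calibration


def _lognormal_sigma_from_iqr(q1: float, q3: float) -> float:
    return float(np.log(q3 / q1) / (2.0 * _Z75))


def _interval_moments(spec: CohortSpec) -> tuple[float, float]:
    """First two moments of the CT interval expressed in years."""
    a, b = spec.interval_min_months / 12.0, spec.interval_max_months / 12.0
    return (a + b) / 2.0, (b**3 - a**3) / (3.0 * (b - a))


def _abs_delta_pearson(rho_z: float, sx: float, sy: float, et: float, et2: float) -> float:
    """Population Pearson correlation of (T·X, T·Y).

    X, Y lognormal with latent correlation ``rho_z`` and sigmas ``sx, sy``;
    T the shared interval factor with moments ``et, et2``; T independent of
    (X, Y). Means of X, Y cancel.
    """
    cov = et2 * np.exp(rho_z * sx * sy) - et**2
    vx = et2 * np.exp(sx**2) - et**2
    vy = et2 * np.exp(sy**2) - et**2
    return float(cov / np.sqrt(vx * vy))


def _solve_latent_rho(target: float, sx: float, sy: float, et: float, et2: float) -> float:
    lo, hi = -0.99999, 0.99999
    rlo, rhi = (_abs_delta_pearson(r, sx, sy, et, et2) for r in (lo, hi))
    if not rlo <= target <= rhi:
        raise ValueError(
            f"target correlation {target} not attainable with margins "
            f"sigma=({sx:.3g}, {sy:.3g}); attainable range [{rlo:.3f}, {rhi:.3f}]"
        )
    return float(brentq(lambda r: _abs_delta_pearson(r, sx, sy, et, et2) - target, lo, hi))


# fraction of the CT1 value by which PWS / PWRI change per year at the median
# (anchored to the reported 12-month-normalized changes relative to CT1 levels)
_PWS_ANNUAL_FRACTION = 0.067
_PWRI_ANNUAL_FRACTION = 0.083


@functools.lru_cache(maxsize=8)
def _calibration(spec: CohortSpec) -> dict:
    """Template-geometry calibration of the change-rate copula (deterministic)."""
    p = _baseline_params(None)
    model, _ = _build_ct1(p)
    from aaamotion.geometry import max_diameter

    dmax1, _ = max_diameter(model, "outer")
    # median annual volume rate: one median year of diameter growth on the template
    s_year = 1.0 + spec.growth_median / dmax1
    mask = _aaa_region(model.centerline)
    _, v1, _ = volumes(model)
    outer = np.where(mask, model.outer_radius * s_year, model.outer_radius)
    v_grown = volumes(VesselModel(model.centerline, model.lumen_radius, outer))[1]
    mu_v = float(np.log(v_grown - v1))
    sigma_v = _lognormal_sigma_from_iqr(spec.growth_q1, spec.growth_q3)

    bm = biomech_metrics(stress_field(model), model)
    mu_p = float(np.log(_PWS_ANNUAL_FRACTION * bm.pws))
    mu_w = float(np.log(_PWRI_ANNUAL_FRACTION * bm.pwri))

    et, et2 = _interval_moments(spec)
    r_vp = _solve_latent_rho(spec.rho_vol_pws, sigma_v, spec.pws_rate_sigma, et, et2)
    r_vw = _solve_latent_rho(spec.rho_vol_pwri, sigma_v, spec.pwri_rate_sigma, et, et2)
    r_pw = _solve_latent_rho(spec.rho_pws_pwri, spec.pws_rate_sigma, spec.pwri_rate_sigma, et, et2)
    corr = np.array([[1.0, r_vp, r_vw], [r_vp, 1.0, r_pw], [r_vw, r_pw, 1.0]])
    eig = np.linalg.eigvalsh(corr)
    if eig.min() <= 0:
        raise ValueError(
            f"latent correlation matrix not positive definite (eigenvalues {eig}); "
            "requested correlation targets are jointly infeasible"
        )
    return dict(
        mu_v=mu_v,
        sigma_v=sigma_v,
        mu_p=mu_p,
        sigma_p=spec.pws_rate_sigma,
        mu_w=mu_w,
        sigma_w=spec.pwri_rate_sigma,
        chol=np.linalg.cholesky(corr),
    )


def draw_change_table(spec: CohortSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-patient change structure only (no geometry).

    Returns a DataFrame with the CT interval, the correlated absolute deltas
    of vessel volume / PWS / PWRI, and the three independent motion
    magnitudes — the sampling core that :func:`simulate_patient` realizes
    geometrically. Useful for cohort-level calibration studies at scale.
    """
    cal = _calibration(spec)
    t_years = rng.uniform(spec.interval_min_months, spec.interval_max_months, n) / 12.0
    z = rng.standard_normal((n, 3)) @ cal["chol"].T
    rate_v = np.exp(cal["mu_v"] + cal["sigma_v"] * z[:, 0])
    rate_p = np.exp(cal["mu_p"] + cal["sigma_p"] * z[:, 1])
    rate_w = np.exp(cal["mu_w"] + cal["sigma_w"] * z[:, 2])
    ms = spec.motion
    motions = np.exp(np.log(ms.median_mm) + ms.sigma * rng.standard_normal((n, 3)))
    return pd.DataFrame(
        {
            "interval_months": t_years * 12.0,
            "delta_vessel_volume": rate_v * t_years,
            "delta_pws": rate_p * t_years,
            "delta_pwri": rate_w * t_years,
            "motion_max_ilt": motions[:, 0],
            "motion_max_pws": motions[:, 1],
            "motion_max_pwri": motions[:, 2],
        }
    )


# ----------------------------------------------------------------------------
# planted transform and landmarks


def _rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    ang = np.radians(rng.uniform(-max_deg, max_deg, 3))
    cx, sx = np.cos(ang[0]), np.sin(ang[0])
    cy, sy = np.cos(ang[1]), np.sin(ang[1])
    cz, sz = np.cos(ang[2]), np.sin(ang[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _planted_transform(rng: np.random.Generator, ts: TransformSpec) -> LinearTransform:
    R = _rotation(rng, ts.rotation_deg)
    t = rng.uniform(-ts.translation_mm, ts.translation_mm, 3)
    if ts.family == "rigid":
        A = R
    elif ts.family == "similarity":
        A = float(rng.uniform(*ts.scale_range)) * R
    else:
        E = rng.uniform(-ts.shear, ts.shear, (3, 3))
        np.fill_diagonal(E, 0.0)
        A = R @ (float(rng.uniform(*ts.scale_range)) * (np.eye(3) + E))
    return LinearTransform(A, t, ts.family, 0.0)


def _fit_landmark_offsets(c: Centerline, rng: np.random.Generator) -> list[Landmark]:
    """Nine fixpoints at anatomically ordered offsets from the centerline."""
    arc = c.arclength
    pts = c.points

    def at(s_mm: float) -> np.ndarray:
        return pts[int(np.searchsorted(arc, s_mm))]

    bif = pts[c.stations["aortic_bifurcation"]]
    spots = {
        "sma": at(18.0) + [0.0, -18.0, 0.0],
        "left_renal": at(_S_RENAL) + [-16.0, 2.0, 0.0],
        "right_renal": at(_S_RENAL) + [16.0, -1.0, 0.0],
        "lumbar_1": at(70.0) + [0.0, 20.0, 0.0],
        "lumbar_2": at(90.0) + [2.0, 21.0, 0.0],
        "lumbar_3": at(110.0) + [-2.0, 20.0, 0.0],
        "aortic_bifurcation": bif + [0.0, 0.0, 0.0],
        "left_cia": bif + [-18.0, 3.0, -18.0],
        "right_cia": bif + [18.0, 3.0, -18.0],
    }
    out = [
        Landmark(lab, np.asarray(pos) + rng.normal(0.0, 2.0, 3), "fit")
        for lab, pos in spots.items()
    ]
    out.append(Landmark("validation", at(120.0) + [0.0, -15.0, 0.0] + rng.normal(0, 2.0, 3), "validation"))
    return out


def _surface_point_and_frame(m: VesselModel, idx: int, rng: np.random.Generator):
    """Surface point at a station plus (tangent, circumferential) surface frame."""
    pts = m.centerline.points
    j = min(idx + 1, len(pts) - 1)
    t = pts[j] - pts[j - 1]
    t = t / np.linalg.norm(t)
    phi = rng.uniform(0.0, 2 * np.pi)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(t, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t, e1)
    n = np.cos(phi) * e1 + np.sin(phi) * e2
    point = pts[idx] + m.outer_radius[idx] * n
    circ = np.cross(t, n)
    return point, t, circ / np.linalg.norm(circ)


def _tangential_motion(
    T: LinearTransform, tangent: np.ndarray, circ: np.ndarray, magnitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """A CT2-frame vector of given norm in the transformed tangent plane."""
    u1 = T.matrix @ tangent
    u1 = u1 / np.linalg.norm(u1)
    u2 = T.matrix @ circ
    u2 = u2 - np.dot(u2, u1) * u1
    u2 = u2 / np.linalg.norm(u2)
    theta = rng.uniform(0.0, 2 * np.pi)
    return magnitude * (np.cos(theta) * u1 + np.sin(theta) * u2)


# ----------------------------------------------------------------------------
# patient and cohort simulation


def _metrics_row(model: VesselModel, iliac: Centerline) -> dict:
    g = compute_geometric_metrics(model, iliac)
    return dict(
        max_diameter=g.max_diameter,
        alpha_angle=g.alpha_angle,
        beta_angle=g.beta_angle,
        neck_length=g.neck_length,
        neck_diameter=g.neck_diameter,
        aortic_tortuosity=g.aortic_tortuosity,
        iliac_tortuosity=g.iliac_tortuosity,
        max_lumen_diameter=g.max_lumen_diameter,
        max_ilt_thickness=g.max_ilt_thickness,
        lumen_volume=g.lumen_volume,
        vessel_volume=g.vessel_volume,
        ilt_volume=g.ilt_volume,
    )


def simulate_patient(spec: CohortSpec, patient_index: int) -> SyntheticPatient:
    """Generate one synthetic paired-timepoint patient.

    Fully reproducible from ``(spec.seed, patient_index)``; the same pair
    always yields bit-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, patient_index]))
    p = _baseline_params(rng)
    ct1, iliac1 = _build_ct1(p)
    age = float(rng.uniform(60.0, 80.0))

    changes = draw_change_table(spec, 1, rng).iloc[0]
    interval = float(changes["interval_months"])
    # mild interval remodeling of the CT2 centerline: the neck angulates a
    # little further and the course gets slightly more tortuous
    p2 = dict(p)
    p2["alpha_bend"] = p["alpha_bend"] + float(rng.normal(0.4, 1.5))
    p2["beta_bend"] = p["beta_bend"] + float(rng.normal(2.0, 2.0))
    p2["wiggle_x"] = p["wiggle_x"] + float(rng.normal(0.0, 0.3))
    p2["wiggle_y"] = p["wiggle_y"] + float(rng.normal(0.0, 0.3))
    ct2_base, _ = _build_ct1(p2)
    delta_v = float(changes["delta_vessel_volume"]) + volumes(ct1)[1] - volumes(ct2_base)[1]
    ct2, _scale = grow_model(ct2_base, delta_v)
    iliac2 = _iliac_centerline(p, iliac1.points[0], p["iliac_amp"] + float(rng.normal(0.4, 0.5)))

    T = _planted_transform(rng, spec.transform)

    # CT1 landmarks: nine fixpoints + validation + three maximum points
    lms1 = _fit_landmark_offsets(ct1.centerline, rng)
    from aaamotion.geometry import max_ilt_thickness as _milt

    _, i_ilt = _milt(ct1)
    bm1 = biomech_metrics(stress_field(ct1), ct1)
    max_stations = {"max_ilt": i_ilt, "max_pws": bm1.pws_index, "max_pwri": bm1.pwri_index}
    frames = {}
    for lab, idx in max_stations.items():
        pos, tangent, circ = _surface_point_and_frame(ct1, idx, rng)
        frames[lab] = (tangent, circ)
        lms1.append(Landmark(lab, pos, "maxpoint"))

    true_motions = {
        "max_ilt": float(changes["motion_max_ilt"]),
        "max_pws": float(changes["motion_max_pws"]),
        "max_pwri": float(changes["motion_max_pwri"]),
    }

    lms2 = []
    for lm in lms1:
        mapped = T.apply(lm.position)
        if lm.role in ("fit", "validation"):
            mapped = mapped + rng.normal(0.0, spec.landmark_noise_sd, 3)
        else:
            tangent, circ = frames[lm.label]
            mapped = mapped + _tangential_motion(T, tangent, circ, true_motions[lm.label], rng)
        lms2.append(Landmark(lm.label, mapped, lm.role))

    row1 = _metrics_row(ct1, iliac1)
    row2 = _metrics_row(ct2, iliac2)
    row2["pws"] = bm1.pws + float(changes["delta_pws"])
    row2["pwri"] = bm1.pwri + float(changes["delta_pwri"])
    row1["pws"], row1["pwri"] = bm1.pws, bm1.pwri

    record = {"patient_id": f"P{patient_index:03d}", "interval_months": interval, "age_years": age}
    for k, v in row1.items():
        record[f"{k}_ct1"] = v
    for k, v in row2.items():
        record[f"{k}_ct2"] = v
    record["motion_max_ilt"] = true_motions["max_ilt"]
    record["motion_max_pws"] = true_motions["max_pws"]
    record["motion_max_pwri"] = true_motions["max_pwri"]
    record["true_growth_rate"] = (row2["max_diameter"] - row1["max_diameter"]) * 12.0 / interval

    return SyntheticPatient(
        patient_id=record["patient_id"],
        interval_months=interval,
        age_years=age,
        ct1_model=ct1,
        ct2_model=ct2,
        ct1_iliac=iliac1,
        ct2_iliac=iliac2,
        ct1_landmarks=lms1,
        ct2_landmarks=lms2,
        transform=T,
        true_motions=true_motions,
        record=record,
    )


def simulate_cohort(spec: CohortSpec) -> tuple[list, pd.DataFrame]:
    """Generate a full cohort and its per-patient record table.

    Returns ``(patients, records)``; the record table uses the same schema the
    analysis pipeline consumes. For a single-patient cohort no correlation
    structure is observable; a warning is logged.
    """
    if spec.n_patients == 1:
        import logging

        logging.getLogger(__name__).warning(
            "simulate_cohort: n_patients = 1; no cohort-level correlation is defined"
        )
    patients = [simulate_patient(spec, i) for i in range(spec.n_patients)]
    records = pd.DataFrame([p.record for p in patients])
    return patients, records
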