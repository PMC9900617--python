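"""Least-squares linear transformation between paired anatomical landmark sets.

The inter-timepoint mapping CT1 → CT2 is estimated from 4-9 corresponding
fixpoints (renal arteries, SMA, aortic bifurcation, iliac and lumbar arteries),
validated against one held-out landmark with a strict 15 mm acceptance gate,
and then used to project the points of maximum ILT thickness, peak wall stress
and peak wall rupture index into the CT2 frame, where their spatial motion is
measured as a Euclidean distance.

Three transformation families are supported:

``rigid``
    Rotation + translation (orthogonal Procrustes / Kabsch).
``similarity``
    Uniform scale × rotation + translation (Umeyama).
``affine``
    Full 12-parameter linear map, the default: aneurysm growth implies
    non-rigid landmark motion, and the fixpoint cloud spans the growing sac.

All solutions minimise the sum of squared residuals over the fit pairs within
their parameter family. Coordinates are world/scanner millimetres in a single
right-handed convention shared by both timepoints; the method is insensitive
to which convention (LPS/RAS) as long as it is the same one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

Mode = Literal["rigid", "similarity", "affine"]

#: Roles a landmark can play in the analysis.
ROLES = ("fit", "validation", "maxpoint")

#: Labels of the tracked maximum points.
MAXPOINT_LABELS = ("max_ilt", "max_pws", "max_pwri")

#: Condition-number bound on the centred source design matrix; beyond this the
#: configuration is treated as degenerate (coplanar/collinear fixpoints).
DEFAULT_CONDITION_BOUND = 1e6

#: Validation gate from the study protocol: the transformation is accepted
#: only if the predicted validation point lands strictly closer than this to
#: its actual CT2 position.
DEFAULT_GATE_MM = 15.0


class DegenerateGeometryError(ValueError):
    """Fit landmarks are (near-)coplanar or collinear for the requested mode."""


class TooFewPairsError(ValueError):
    """Not enough fit pairs for the requested transformation family."""


class GateError(RuntimeError):
    """Motion analysis requested on a transformation that failed validation."""


@dataclass(frozen=True)
class Landmark:
    """A labelled anatomical point for one patient-timepoint."""

    label: str
    position: np.ndarray  # (3,), mm
    role: str = "fit"

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"landmark {self.label!r}: position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"landmark {self.label!r}: non-finite coordinates")
        if self.role not in ROLES:
            raise ValueError(f"landmark {self.label!r}: unknown role {self.role!r}")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class CorrespondenceSet:
    """Paired CT1/CT2 landmark coordinates for one patient.

    ``fit_pairs`` drive the least-squares fit, the single ``validation_pair``
    is held out to gate the transformation, and ``maxpoint_pairs`` carry the
    tracked maxima whose motion is measured.
    Each pair is ``(source_xyz, target_xyz, label)`` with positions in mm.
    """

    patient_id: str
    fit_pairs: tuple
    validation_pair: tuple | None = None
    maxpoint_pairs: tuple = ()

    def __post_init__(self) -> None:
        fit = tuple(
            (np.asarray(s, float), np.asarray(t, float), str(lab))
            for s, t, lab in self.fit_pairs
        )
        object.__setattr__(self, "fit_pairs", fit)
        if not 4 <= len(fit) <= 9:
            # the affine minimum; rigid/similarity accept 3 via estimate_transform
            if len(fit) < 3 or len(fit) > 9:
                raise TooFewPairsError(
                    f"patient {self.patient_id}: {len(fit)} fit pairs; need 3-9"
                )
        labels = [lab for _, _, lab in fit]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"patient {self.patient_id}: duplicate fit labels {dupes}")
        if self.validation_pair is not None:
            s, t, lab = self.validation_pair
            if lab in labels:
                raise ValueError(
                    f"patient {self.patient_id}: validation label {lab!r} also "
                    "appears among fit labels; the validation point must be held out"
                )
            object.__setattr__(
                self,
                "validation_pair",
                (np.asarray(s, float), np.asarray(t, float), str(lab)),
            )
        mp = tuple(
            (np.asarray(s, float), np.asarray(t, float), str(lab))
            for s, t, lab in self.maxpoint_pairs
        )
        if len(mp) > 3:
            raise ValueError(f"patient {self.patient_id}: at most 3 maxpoint pairs")
        object.__setattr__(self, "maxpoint_pairs", mp)

    @property
    def source_fit(self) -> np.ndarray:
        return np.array([s for s, _, _ in self.fit_pairs])

    @property
    def target_fit(self) -> np.ndarray:
        return np.array([t for _, t, _ in self.fit_pairs])

    @property
    def fit_labels(self) -> list[str]:
        return [lab for _, _, lab in self.fit_pairs]


@dataclass(frozen=True)
class LinearTransform:
    """Affine map ``p ↦ matrix @ p + translation`` from CT1 into CT2 space."""

    matrix: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,), mm
    mode: Mode = "affine"
    fit_rms: float = 0.0  # RMS residual over fit pairs, mm

    def __post_init__(self) -> None:
        A = np.asarray(self.matrix, float)
        t = np.asarray(self.translation, float)
        if A.shape != (3, 3) or t.shape != (3,):
            raise ValueError("matrix must be 3x3 and translation a 3-vector")
        if self.fit_rms < 0:
            raise ValueError("fit_rms must be >= 0")
        if self.mode in ("rigid", "similarity"):
            s = np.linalg.det(A) ** (1.0 / 3.0) if self.mode == "similarity" else 1.0
            R = A / s
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
                raise ValueError(f"{self.mode} matrix is not (scaled) orthogonal")
            if np.linalg.det(R) < 0:
                raise ValueError(f"{self.mode} matrix has negative determinant")
        object.__setattr__(self, "matrix", A)
        object.__setattr__(self, "translation", t)

    def apply(self, p: np.ndarray) -> np.ndarray:
        return apply_transform(self, p)

    def inverse(self) -> "LinearTransform":
        Ainv = np.linalg.inv(self.matrix)
        return LinearTransform(Ainv, -Ainv @ self.translation, self.mode, self.fit_rms)


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of the held-out validation-point gate."""

    distance: float  # mm
    threshold: float  # mm
    accepted: bool

    def __post_init__(self) -> None:
        if self.accepted != (self.distance < self.threshold):
            raise ValueError("accepted flag inconsistent with strict distance rule")


@dataclass(frozen=True)
class MotionResult:
    """Spatial motion of one tracked maximum point, measured in CT2 space."""

    label: str
    predicted_position: np.ndarray  # mm, CT2 frame
    actual_position: np.ndarray  # mm, CT2 frame
    distance: float  # mm


def _check_geometry(
    src: np.ndarray, mode: Mode, labels: Sequence[str], condition_bound: float
) -> None:
    """Raise if the centred source cloud is too flat for the requested family."""
    centred = src - src.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    # affine needs full 3-D spread; rigid/similarity only need non-collinearity
    k = 2 if mode == "affine" else 1
    if sv[k] == 0 or sv[0] / sv[k] > condition_bound:
        shape = "coplanar" if mode == "affine" else "collinear"
        raise DegenerateGeometryError(
            f"fit landmarks {list(labels)} are (near-){shape}: "
            f"condition number {np.inf if sv[k] == 0 else sv[0] / sv[k]:.3g} "
            f"exceeds bound {condition_bound:.3g} for mode {mode!r}"
        )


def _procrustes(src: np.ndarray, dst: np.ndarray, scale: bool) -> tuple[np.ndarray, np.ndarray]:
    """Kabsch/Umeyama solution: least-squares (scaled) rotation + translation."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    X, Y = src - mu_s, dst - mu_d
    H = X.T @ Y
    U, D, Vt = np.linalg.svd(H)
    # proper rotation: flip the smallest singular direction if det < 0
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    S = np.diag([1.0, 1.0, d])
    R = Vt.T @ S @ U.T
    if scale:
        var_x = (X**2).sum()
        s = float((D * np.diag(S)).sum() / var_x)
        A = s * R
    else:
        A = R
    t = mu_d - A @ mu_s
    return A, t


def _affine_lstsq(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full 12-parameter least-squares affine fit via the homogeneous design."""
    n = len(src)
    X = np.hstack([src, np.ones((n, 1))])  # (n, 4)
    coef, *_ = np.linalg.lstsq(X, dst, rcond=None)  # (4, 3)
    A = coef[:3].T
    t = coef[3]
    return A, t


def estimate_transform(
    corr: CorrespondenceSet,
    mode: Mode = "affine",
    condition_bound: float = DEFAULT_CONDITION_BOUND,
) -> LinearTransform:
    """Fit the CT1→CT2 transformation to the fixpoint correspondences.

    Minimises the sum of squared coordinate residuals over the fit pairs
    within the requested family. Deterministic given its inputs.

    Raises
    ------
    TooFewPairsError
        Fewer than 4 (affine) or 3 (rigid/similarity) fit pairs.
    DegenerateGeometryError
        Fit landmarks near-coplanar (affine) or near-collinear, judged by the
        condition number of the centred source matrix.
    """
    if mode not in ("rigid", "similarity", "affine"):
        raise ValueError(f"unknown mode {mode!r}")
    src, dst = corr.source_fit, corr.target_fit
    minimum = 4 if mode == "affine" else 3
    if len(src) < minimum:
        raise TooFewPairsError(
            f"patient {corr.patient_id}: mode {mode!r} needs >= {minimum} fit "
            f"pairs, got {len(src)}"
        )
    _check_geometry(src, mode, corr.fit_labels, condition_bound)
    if mode == "affine":
        A, t = _affine_lstsq(src, dst)
    else:
        A, t = _procrustes(src, dst, scale=(mode == "similarity"))
    resid = (src @ A.T + t) - dst
    rms = float(np.sqrt((resid**2).sum() / len(src)))
    return LinearTransform(A, t, mode, rms)


def apply_transform(T: LinearTransform, p: np.ndarray) -> np.ndarray:
    """Map one point or an (n, 3) array of points from CT1 into CT2 space."""
    p = np.asarray(p, float)
    if p.ndim == 1:
        return T.matrix @ p + T.translation
    return p @ T.matrix.T + T.translation


def validate_transform(
    T: LinearTransform, corr: CorrespondenceSet, threshold: float = DEFAULT_GATE_MM
) -> ValidationResult:
    """Gate the transformation on the held-out validation landmark.

    The transformation is accepted iff the Euclidean distance between the
    predicted and actual CT2 validation positions is strictly below
    ``threshold`` (default 15 mm, the study inclusion rule).
    """
    if corr.validation_pair is None:
        raise ValueError(f"patient {corr.patient_id}: no validation pair present")
    s, t, _ = corr.validation_pair
    d = float(np.linalg.norm(apply_transform(T, s) - t))
    return ValidationResult(distance=d, threshold=threshold, accepted=d < threshold)


def maxpoint_motion(
    T: LinearTransform,
    corr: CorrespondenceSet,
    validation: ValidationResult | None = None,
    override_gate: bool = False,
) -> list[MotionResult]:
    """Project the CT1 maximum points into CT2 and measure their motion.

    One :class:`MotionResult` per maxpoint pair; the distance is Euclidean and
    lives in CT2 coordinates. If a failed :class:`ValidationResult` is passed,
    the call is refused unless ``override_gate`` is set (the override is noted
    on stderr via a warning so it is never silent).
    """
    if not corr.maxpoint_pairs:
        raise ValueError(f"patient {corr.patient_id}: no maxpoint pairs present")
    if validation is not None and not validation.accepted:
        if not override_gate:
            raise GateError(
                f"patient {corr.patient_id}: transformation failed the "
                f"{validation.threshold} mm validation gate "
                f"(distance {validation.distance:.2f} mm); pass "
                "override_gate=True to measure motion anyway"
            )
        import warnings

        warnings.warn(
            f"patient {corr.patient_id}: measuring motion despite failed "
            f"validation gate ({validation.distance:.2f} mm)",
            stacklevel=2,
        )
    out = []
    for s, tgt, lab in corr.maxpoint_pairs:
        pred = apply_transform(T, s)
        out.append(
            MotionResult(
                label=lab,
                predicted_position=pred,
                actual_position=tgt,
                distance=float(np.linalg.norm(pred - tgt)),
            )
        )
    return out
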