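"""File formats: landmark CSV, vessel-model JSON, transform reports, tables.

All text formats are fixed-dialect: comma-separated, dot decimal, UTF-8,
mandatory header row. Coordinates are world/scanner millimetres in one
declared axis convention per dataset; the loader never converts between
conventions, it only asserts that a single one is declared.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from aaamotion.geometry import Centerline, VesselModel
from aaamotion.registration import (
    CorrespondenceSet,
    Landmark,
    LinearTransform,
    MotionResult,
    ValidationResult,
)

LANDMARK_COLUMNS = ["patient_id", "timepoint", "label", "role", "x_mm", "y_mm", "z_mm"]
TIMEPOINTS = ("ct1", "ct2")

MODEL_SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Input file violates the declared schema."""


def read_landmarks(path) -> dict:
    """Read a landmark CSV into ``{(patient_id, timepoint): [Landmark, ...]}``.

    Validates the schema row by row and reports every offending row number
    (1-based, header excluded) in one error.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    problems = []
    for i, row in df.iterrows():
        rowno = i + 1
        if row["timepoint"] not in TIMEPOINTS:
            problems.append(f"row {rowno}: timepoint {row['timepoint']!r} not in {TIMEPOINTS}")
        if row["role"] not in ("fit", "validation", "maxpoint"):
            problems.append(f"row {rowno}: unknown role {row['role']!r}")
        if not all(np.isfinite([row["x_mm"], row["y_mm"], row["z_mm"]])):
            problems.append(f"row {rowno}: non-finite coordinates")
    dupes = df.duplicated(subset=["patient_id", "timepoint", "label"], keep=False)
    for i in df.index[dupes]:
        problems.append(
            f"row {i + 1}: duplicate label {df.loc[i, 'label']!r} for "
            f"{df.loc[i, 'patient_id']}/{df.loc[i, 'timepoint']}"
        )
    if problems:
        raise SchemaError(f"{path}: schema violations:\n  " + "\n  ".join(problems))
    out: dict = {}
    for (pid, tp), grp in df.groupby(["patient_id", "timepoint"], sort=True):
        out[(pid, tp)] = [
            Landmark(r["label"], np.array([r["x_mm"], r["y_mm"], r["z_mm"]]), r["role"])
            for _, r in grp.iterrows()
        ]
    return out


def write_landmarks(sets: dict, path) -> None:
    """Write ``{(patient_id, timepoint): [Landmark, ...]}`` to the landmark CSV."""
    rows = []
    for (pid, tp), lms in sorted(sets.items()):
        for lm in lms:
            rows.append(
                dict(
                    patient_id=pid,
                    timepoint=tp,
                    label=lm.label,
                    role=lm.role,
                    x_mm=lm.position[0],
                    y_mm=lm.position[1],
                    z_mm=lm.position[2],
                )
            )
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


def correspondences_from_sets(
    ct1: list, ct2: list, patient_id: str
) -> CorrespondenceSet:
    """Pair two timepoints' landmark lists by label."""
    by1 = {lm.label: lm for lm in ct1}
    by2 = {lm.label: lm for lm in ct2}
    common = [lab for lab in by1 if lab in by2]
    fit, val, mp = [], None, []
    for lab in common:
        pair = (by1[lab].position, by2[lab].position, lab)
        role = by1[lab].role
        if role == "fit":
            fit.append(pair)
        elif role == "validation":
            val = pair
        else:
            mp.append(pair)
    return CorrespondenceSet(patient_id, tuple(fit), val, tuple(mp))


def write_vessel_model(m: VesselModel, path, iliac: Centerline | None = None) -> None:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "points_mm": m.centerline.points.tolist(),
        "lumen_radius_mm": m.lumen_radius.tolist(),
        "outer_radius_mm": m.outer_radius.tolist(),
        "stations": dict(m.centerline.stations),
    }
    if iliac is not None:
        doc["iliac_points_mm"] = iliac.points.tolist()
        doc["iliac_stations"] = dict(iliac.stations)
    Path(path).write_text(json.dumps(doc))


def read_vessel_model(path) -> tuple[VesselModel, Centerline | None]:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise SchemaError(f"{path}: unsupported schema version {doc.get('schema_version')}")
    c = Centerline(np.array(doc["points_mm"]), {k: int(v) for k, v in doc["stations"].items()})
    m = VesselModel(c, np.array(doc["lumen_radius_mm"]), np.array(doc["outer_radius_mm"]))
    iliac = None
    if "iliac_points_mm" in doc:
        iliac = Centerline(
            np.array(doc["iliac_points_mm"]),
            {k: int(v) for k, v in doc.get("iliac_stations", {}).items()},
        )
    return m, iliac


def transform_report(
    T: LinearTransform,
    validation: ValidationResult | None,
    motions: list | None,
) -> dict:
    """JSON-ready report of one patient's registration outcome."""
    doc = {
        "mode": T.mode,
        "matrix_row_major": [float(x) for x in T.matrix.ravel()],
        "translation_mm": [float(x) for x in T.translation],
        "fit_rms_mm": T.fit_rms,
    }
    if validation is not None:
        doc["validation_distance_mm"] = validation.distance
        doc["validation_threshold_mm"] = validation.threshold
        doc["accepted"] = validation.accepted
    if motions is not None:
        doc["motion_distances_mm"] = {m.label: m.distance for m in motions}
    return doc
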