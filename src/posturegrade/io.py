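"""Readers and writers: cohort CSV, landmark JSON, depth-map PGM, model JSON.

File conventions are fixed to avoid locale drift: CSV is UTF-8,
comma-separated, '.' decimal, header required. Landmark JSON follows the
schema shipped at ``posturegrade/data/landmark_schema.json`` (pixels, y-up).
Depth maps are 16-bit binary (P5) PGM with depth in millimetres.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .geometry import (
    FEATURE_NAMES,
    CoronalLandmarks,
    DepthMap,
    Point2D,
    SagittalLandmarks,
    compute_features,
)

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "read_landmarks_json",
    "write_landmarks_json",
    "extract_features",
    "read_depth_pgm",
    "write_depth_pgm",
]

_SAGITTAL_KEYS = ("MH", "MN", "C7", "FC", "L5", "LM")
_CORONAL_KEYS = ("MH", "MN", "C7", "L5")


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table (subject_id, F1..F8, score[, score2]).

    Scores are validated to lie in 0..4; a malformed numeric cell raises a
    parse error naming the data line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise InvalidInputError(f"{path}: empty cohort file") from exc
    required = {"subject_id", "score"} | set(FEATURE_NAMES)
    missing = sorted(required - set(df.columns))
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    numeric_cols = [*FEATURE_NAMES, "score"] + (["score2"] if "score2" in df else [])
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise InvalidInputError(f"{path}: malformed value in column {col}, line {line}")
        df[col] = coerced
    for col in ("score", "score2"):
        if col in df and not df[col].isin(range(5)).all():
            bad_line = int((~df[col].isin(range(5))).idxmax()) + 2
            raise InvalidInputError(f"{path}: {col} outside 0..4 at line {bad_line}")
    df["score"] = df["score"].astype(int)
    if "score2" in df:
        df["score2"] = df["score2"].astype(int)
    return df


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# landmark JSON
# ---------------------------------------------------------------------------


def _parse_landmarks(record: dict) -> SagittalLandmarks | CoronalLandmarks:
    plane = record.get("plane")
    subject = record.get("subject_id", "<unknown>")
    keys = _SAGITTAL_KEYS if plane == "sagittal" else _CORONAL_KEYS
    lm = record.get("landmarks", {})
    pts = {}
    for key in keys:
        if key not in lm:
            raise InvalidInputError(
                f"subject {subject}: missing landmark {key} on the {plane} plane"
            )
        x, y = lm[key]
        pts[key] = Point2D(float(x), float(y))
    cls = SagittalLandmarks if plane == "sagittal" else CoronalLandmarks
    return cls(**pts)


def read_landmarks_json(path) -> dict[str, dict[str, object]]:
    """Read a landmark file into {subject_id: {plane: landmark set}}."""
    records = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(records, list):
        raise InvalidInputError("landmark file must contain a JSON array")
    out: dict[str, dict[str, object]] = {}
    for rec in records:
        plane = rec.get("plane")
        if plane not in ("sagittal", "coronal"):
            raise InvalidInputError(f"unknown plane {plane!r} in landmark file")
        out.setdefault(rec["subject_id"], {})[plane] = _parse_landmarks(rec)
    return out


def write_landmarks_json(subjects: dict[str, dict[str, object]], path) -> None:
    """Inverse of :func:`read_landmarks_json`."""
    records = []
    for subject_id in subjects:
        for plane, lms in subjects[subject_id].items():
            records.append(
                {
                    "subject_id": subject_id,
                    "plane": plane,
                    "landmarks": {k: [p.x, p.y] for k, p in lms.items()},
                }
            )
    Path(path).write_text(json.dumps(records, indent=1), encoding="utf-8")


def extract_features(
    subjects: dict[str, dict[str, object]]
) -> tuple[pd.DataFrame, list[str]]:
    """Compute the feature table from per-subject landmark sets.

    Subjects missing one of the two planes are skipped and listed in the
    returned skip report rather than aborting the batch.
    """
    rows = []
    skipped: list[str] = []
    for subject_id, planes in subjects.items():
        if "sagittal" not in planes or "coronal" not in planes:
            skipped.append(subject_id)
            continue
        fv = compute_features(planes["sagittal"], planes["coronal"])
        rows.append({"subject_id": subject_id, **fv.as_dict()})
    columns = ["subject_id", *FEATURE_NAMES]
    df = pd.DataFrame(rows, columns=columns)
    return df, skipped


# ---------------------------------------------------------------------------
# depth maps (16-bit binary PGM)
# ---------------------------------------------------------------------------


def read_depth_pgm(path) -> DepthMap:
    """Read a 16-bit grayscale binary PGM depth frame (depth in mm)."""
    import imageio.v3 as iio

    values = np.asarray(iio.imread(Path(path)))
    if values.ndim != 2:
        raise InvalidInputError(f"{path}: expected a single-channel PGM")
    return DepthMap(values=values.astype(float))


def write_depth_pgm(dm: DepthMap, path) -> None:
    import imageio.v3 as iio

    v = dm.values
    if np.any(v > 65535):
        raise InvalidInputError("depth exceeds the 16-bit PGM range")
    iio.imwrite(Path(path), np.round(v).astype(np.uint16))
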