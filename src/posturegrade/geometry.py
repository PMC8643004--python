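"""Trunk-posture geometry: landmarks, the eight quantified features, and depth-map segmentation.

The eight features grade postural abnormality in Parkinson's disease
(MDS-UPDRS-III item 3.13). Coronal-plane features capture Pisa-syndrome-like
lateral flexion, sagittal-plane features capture camptocormia-like forward
flexion:

======= ======== ==========================================================
feature plane    definition
======= ======== ==========================================================
F1      coronal  lateral head flexion: MN->MH vs the vertical of the ground
F2      coronal  lateral trunk flexion: L5->C7 vs the vertical
F3      sagittal forward head flexion: MN->MH vs the vertical
F4      sagittal total trunk flexion: L5->C7 vs the leg axis LM->L5
F5      sagittal waist flexion: L5->FC vs the leg axis LM->L5
F6      sagittal thoracic flexion: FC->C7 vs L5->FC
F7      sagittal camptocormia convexity: distance of FC from the C7-L5
                 chord, as a percentage of body height (MH.y - LM.y)
F8      sagittal head-on-trunk flexion: MN->MH vs L5->C7
======= ======== ==========================================================

Landmarks: MH midpoint of head, MN midpoint of neck, C7 / L5 the 7th
cervical / 5th lumbar spinous processes, FC the vertebral fulcrum (most
convex point of the back), LM the lateral malleolus.

Coordinate convention: 2D planes use y increasing *upward*; the vertical of
the ground is the +y axis, so "angle to vertical" is a plain dot product.
Image-row (y-down) conventions are confined to the I/O layer. All angles are
unsigned magnitudes in [0, 180] degrees; the severity scale has no
left/right sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Literal, Mapping, NamedTuple

import numpy as np

from .exceptions import (
    DegenerateGeometryError,
    InvalidInputError,
    InvalidPostureError,
)

__all__ = [
    "Point2D",
    "Point3D",
    "Skeleton25",
    "SagittalLandmarks",
    "CoronalLandmarks",
    "FeatureVector",
    "FEATURE_NAMES",
    "DepthMap",
    "SegmentationParams",
    "project_joint",
    "project_skeleton",
    "angle_to_vertical",
    "angle_between_directed_segments",
    "point_to_line_distance",
    "body_height_px",
    "compute_features",
    "segment_body",
]

FEATURE_NAMES: tuple[str, ...] = ("F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8")

#: number of 3D joints delivered by the skeleton tracker
N_SKELETON_JOINTS = 25


class Point2D(NamedTuple):
    """Plane point in pixels, y increasing upward."""

    x: float
    y: float


class Point3D(NamedTuple):
    """Camera-frame point in metres (x lateral, y up, z anterior)."""

    x: float
    y: float
    z: float


def _check_finite_2d(p: Point2D, name: str = "point") -> None:
    if not (math.isfinite(p[0]) and math.isfinite(p[1])):
        raise InvalidInputError(f"{name} has non-finite coordinates: {p}")


@dataclass(frozen=True)
class Skeleton25:
    """The 25-joint 3D skeleton produced by the depth-camera tracker.

    Only head, neck and hip are consumed by the posture features; the
    remaining joints are carried as opaque payload so that full tracker
    output round-trips through the package.
    """

    joints: Mapping[str, Point3D]

    def __post_init__(self) -> None:
        if len(self.joints) != N_SKELETON_JOINTS:
            raise InvalidInputError(
                f"skeleton must contain exactly {N_SKELETON_JOINTS} joints, "
                f"got {len(self.joints)}"
            )
        for name, j in self.joints.items():
            if not all(math.isfinite(c) for c in j):
                raise InvalidInputError(f"joint {name!r} has non-finite coordinates")


def project_joint(joint: Point3D, plane: Literal["sagittal", "coronal"]) -> Point2D:
    """Orthographic projection of a 3D joint onto an anatomical plane.

    The sagittal (side) view keeps (z_anterior, y_up); the coronal (front)
    view keeps (x_lateral, y_up). The vertical coordinate is preserved
    exactly in both.
    """
    if not all(math.isfinite(c) for c in joint):
        raise InvalidInputError(f"non-finite joint: {joint}")
    if plane == "sagittal":
        return Point2D(joint.z, joint.y)
    if plane == "coronal":
        return Point2D(joint.x, joint.y)
    raise InvalidInputError(f"unknown plane: {plane!r}")


def project_skeleton(
    skeleton: Skeleton25, plane: Literal["sagittal", "coronal"]
) -> dict[str, Point2D]:
    """Project every joint of a skeleton onto one plane."""
    return {name: project_joint(j, plane) for name, j in skeleton.joints.items()}


@dataclass(frozen=True)
class SagittalLandmarks:
    """Side-view landmarks (pixels, y-up) for an upright subject."""

    MH: Point2D
    MN: Point2D
    C7: Point2D
    FC: Point2D
    L5: Point2D
    LM: Point2D

    def __post_init__(self) -> None:
        for name, p in self.items():
            _check_finite_2d(p, f"sagittal {name}")
        if not self.MH.y > self.MN.y:
            raise InvalidPostureError("sagittal MH must lie above MN")
        if not self.C7.y > self.L5.y:
            raise InvalidPostureError("sagittal C7 must lie above L5")
        if not self.L5.y > self.LM.y:
            raise InvalidPostureError("sagittal L5 must lie above LM")

    def items(self) -> Iterator[tuple[str, Point2D]]:
        for name in ("MH", "MN", "C7", "FC", "L5", "LM"):
            yield name, getattr(self, name)


@dataclass(frozen=True)
class CoronalLandmarks:
    """Front-view landmarks (pixels, y-up) for an upright subject."""

    MH: Point2D
    MN: Point2D
    C7: Point2D
    L5: Point2D

    def __post_init__(self) -> None:
        for name, p in self.items():
            _check_finite_2d(p, f"coronal {name}")
        if not self.MH.y > self.MN.y:
            raise InvalidPostureError("coronal MH must lie above MN")
        if not self.C7.y > self.L5.y:
            raise InvalidPostureError("coronal C7 must lie above L5")

    def items(self) -> Iterator[tuple[str, Point2D]]:
        for name in ("MH", "MN", "C7", "L5"):
            yield name, getattr(self, name)


@dataclass(frozen=True)
class FeatureVector:
    """The eight quantified posture features.

    F1-F6 and F8 are angles in degrees, in [0, 180]; F7 is the vertebral
    convexity offset as a percentage of body height, non-negative.
    """

    F1: float
    F2: float
    F3: float
    F4: float
    F5: float
    F6: float
    F7: float
    F8: float

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidInputError(f"{name} is non-finite")
        for name in ("F1", "F2", "F3", "F4", "F5", "F6", "F8"):
            v = getattr(self, name)
            if not 0.0 <= v <= 180.0:
                raise InvalidInputError(f"{name}={v} outside [0, 180] degrees")
        if self.F7 < 0.0:
            raise InvalidInputError(f"F7={self.F7} must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


# ---------------------------------------------------------------------------
# elementary geometry
# ---------------------------------------------------------------------------


def _vector(base: Point2D, tip: Point2D, what: str) -> tuple[float, float]:
    dx, dy = tip[0] - base[0], tip[1] - base[1]
    if dx == 0.0 and dy == 0.0:
        raise DegenerateGeometryError(f"coincident points in {what}: {base}")
    return dx, dy


def angle_to_vertical(base: Point2D, tip: Point2D) -> float:
    """Angle in degrees between the directed segment base->tip and the
    vertical of the ground (+y axis), in [0, 180].

    Defined as arccos(unit(tip - base) . (0, 1)); evaluated in the
    numerically stable atan2 form, which is exact near 0 and 180 where
    arccos of a clamped dot product loses digits.
    """
    _check_finite_2d(base, "base")
    _check_finite_2d(tip, "tip")
    dx, dy = _vector(base, tip, "angle_to_vertical")
    return math.degrees(math.atan2(abs(dx), dy))


def angle_between_directed_segments(
    a_base: Point2D, a_tip: Point2D, b_base: Point2D, b_tip: Point2D
) -> float:
    """Angle in degrees between two directed segments, in [0, 180].

    Body-chain segments are all directed cranially (feet to head), so a
    perfectly straight posture yields 0 for every chain angle. The value is
    arccos of the unit-vector dot product, computed as atan2(|cross|, dot)
    for numerical stability at nearly (anti)parallel segments.
    """
    for p in (a_base, a_tip, b_base, b_tip):
        _check_finite_2d(p)
    ax, ay = _vector(a_base, a_tip, "segment a")
    bx, by = _vector(b_base, b_tip, "segment b")
    cross = ax * by - ay * bx
    dot = ax * bx + ay * by
    return math.degrees(math.atan2(abs(cross), dot))


def point_to_line_distance(p: Point2D, l1: Point2D, l2: Point2D) -> float:
    """Perpendicular distance (pixels) from p to the infinite line l1-l2."""
    for q in (p, l1, l2):
        _check_finite_2d(q)
    dx, dy = _vector(l1, l2, "line")
    n = math.hypot(dx, dy)
    return abs(dx * (p[1] - l1[1]) - dy * (p[0] - l1[0])) / n


def body_height_px(lm: SagittalLandmarks) -> float:
    """Vertical pixel extent of the body, head midpoint to ankle.

    Used to normalize F7 so the convexity offset is comparable across
    subjects of different stature and camera distances.
    """
    h = lm.MH.y - lm.LM.y
    if h <= 0:
        raise InvalidPostureError("non-positive body extent (MH not above LM)")
    return float(h)


def compute_features(sag: SagittalLandmarks, cor: CoronalLandmarks) -> FeatureVector:
    """Compute the eight posture features from one coronal and one sagittal
    landmark set. See the module docstring for the definitions."""
    f1 = angle_to_vertical(cor.MN, cor.MH)
    f2 = angle_to_vertical(cor.L5, cor.C7)
    f3 = angle_to_vertical(sag.MN, sag.MH)
    f4 = angle_between_directed_segments(sag.L5, sag.C7, sag.LM, sag.L5)
    f5 = angle_between_directed_segments(sag.L5, sag.FC, sag.LM, sag.L5)
    f6 = angle_between_directed_segments(sag.FC, sag.C7, sag.L5, sag.FC)
    f7 = 100.0 * point_to_line_distance(sag.FC, sag.C7, sag.L5) / body_height_px(sag)
    f8 = angle_between_directed_segments(sag.MN, sag.MH, sag.L5, sag.C7)
    return FeatureVector(f1, f2, f3, f4, f5, f6, f7, f8)


# ---------------------------------------------------------------------------
# depth-map segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DepthMap:
    """Rectangular grid of depths in millimetres (16-bit depth-camera frame)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise InvalidInputError("depth map must be a non-empty 2-D grid")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise InvalidInputError("depths must be finite and non-negative")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SegmentationParams:
    """Depth gate around the body centre: a pixel belongs to the body iff
    its depth lies strictly within ``thr`` millimetres of ``d_c``."""

    d_c: float
    thr: float

    def __post_init__(self) -> None:
        if not self.thr > 0:
            raise InvalidInputError("segmentation threshold must be > 0")


def segment_body(dm: DepthMap, params: SegmentationParams) -> np.ndarray:
    """Segment the body from a depth frame.

    Returns a boolean mask of the same shape as the depth map, True on body
    pixels: |d(x,y) - d_c| < thr (strict inequality at the boundary).
    """
    return np.abs(dm.values - params.d_c) < params.thr
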