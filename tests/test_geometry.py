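"""Posture-feature geometry: angles, distances, segmentation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import posturegrade as pg
from posturegrade.exceptions import (
    DegenerateGeometryError,
    InvalidInputError,
    InvalidPostureError,
)

P = pg.Point2D


def angle_to_vertical_oracle(base, tip):
    """Definitional oracle: arccos of the unit vector's y component."""
    vx, vy = tip[0] - base[0], tip[1] - base[1]
    n = math.hypot(vx, vy)
    return math.degrees(math.acos(max(-1.0, min(1.0, vy / n))))


def angle_between_oracle(a, b):
    """Definitional oracle: arccos of the unit-vector dot product."""
    na, nb = math.hypot(*a), math.hypot(*b)
    dot = (a[0] * b[0] + a[1] * b[1]) / (na * nb)
    return math.degrees(math.acos(max(-1.0, min(1.0, dot))))


coords = st.floats(-1e3, 1e3)


class TestProjection:
    @pytest.mark.parametrize(
        "joint, plane, expected",
        [
            ((0, 0, 0), "sagittal", (0, 0)),
            ((1, 2, 3), "sagittal", (3, 2)),
            ((1, 2, 3), "coronal", (1, 2)),
        ],
    )
    def test_axis_drop(self, joint, plane, expected):
        assert pg.project_joint(pg.Point3D(*joint), plane) == P(*expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            pg.project_joint(pg.Point3D(float("nan"), 0, 0), "sagittal")

    def test_skeleton_carries_25_joints(self):
        joints = {f"j{i}": pg.Point3D(i, 2 * i, 3.0) for i in range(25)}
        sk = pg.Skeleton25(joints=joints)
        proj = pg.geometry.project_skeleton(sk, "coronal")
        assert len(proj) == 25 and proj["j3"] == P(3, 6)
        with pytest.raises(InvalidInputError):
            pg.Skeleton25(joints=dict(list(joints.items())[:24]))


class TestAngles:
    @pytest.mark.parametrize(
        "base, tip, expected",
        [
            ((0, 0), (0, 10), 0.0),
            ((0, 0), (10, 10), 45.0),
            ((0, 0), (8.749, 100), 5.0),  # tan 5 deg = 0.08749
        ],
    )
    def test_angle_to_vertical(self, base, tip, expected):
        assert pg.angle_to_vertical(P(*base), P(*tip)) == pytest.approx(expected, abs=1e-3)

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            pg.angle_to_vertical(P(1, 1), P(1, 1))
        with pytest.raises(DegenerateGeometryError):
            pg.angle_between_directed_segments(P(0, 0), P(1, 1), P(2, 2), P(2, 2))

    @pytest.mark.parametrize(
        "segs, expected",
        [
            (((0, 0), (0, 1), (0, -1), (0, 0)), 0.0),   # collinear chain
            (((0, 0), (1, 0), (0, 0), (0, 1)), 90.0),   # perpendicular
            (((0, 0), (1, 1), (0, 0), (0, 1)), 45.0),
        ],
    )
    def test_angle_between_segments(self, segs, expected):
        pts = [P(*s) for s in segs]
        assert pg.angle_between_directed_segments(*pts) == pytest.approx(expected, abs=1e-9)

    def test_agrees_with_definitional_oracle_on_random_segments(self):
        """Random segments agree with the arccos-of-dot-product definition
        (to the conditioning limit of arccos near 0/180)."""
        rng = np.random.default_rng(42)
        pts = rng.uniform(-500, 500, size=(2_000, 8))
        for row in pts:
            base, tip = P(row[0], row[1]), P(row[2], row[3])
            if base == tip:
                continue
            assert pg.angle_to_vertical(base, tip) == pytest.approx(
                angle_to_vertical_oracle(base, tip), abs=1e-5
            )
            b2, t2 = P(row[4], row[5]), P(row[6], row[7])
            if b2 == t2:
                continue
            got = pg.angle_between_directed_segments(base, tip, b2, t2)
            want = angle_between_oracle(
                (tip.x - base.x, tip.y - base.y), (t2.x - b2.x, t2.y - b2.y)
            )
            assert got == pytest.approx(want, abs=1e-5)

    @given(bx=coords, by=coords, tx=coords, ty=coords)
    def test_complementary_directions(self, bx, by, tx, ty):
        """Reversing a segment reflects its angle to vertical about 90 deg."""
        base, tip = P(bx, by), P(tx, ty)
        if abs(tx - bx) < 1e-6 and abs(ty - by) < 1e-6:
            return
        fwd = pg.angle_to_vertical(base, tip)
        rev = pg.angle_to_vertical(tip, base)
        assert fwd + rev == pytest.approx(180.0, abs=1e-6)


class TestDistanceAndHeight:
    @pytest.mark.parametrize(
        "p, l1, l2, expected",
        [
            ((0, 50), (0, 0), (0, 100), 0.0),   # on the line
            ((7, 50), (0, 0), (0, 100), 7.0),   # vertical line
            ((0, 5), (0, 0), (3, 4), 3.0),      # |x1 y2 - x2 y1| / |l2 - l1|
        ],
    )
    def test_point_to_line(self, p, l1, l2, expected):
        assert pg.point_to_line_distance(P(*p), P(*l1), P(*l2)) == pytest.approx(expected)

    def test_degenerate_line(self):
        with pytest.raises(DegenerateGeometryError):
            pg.point_to_line_distance(P(1, 1), P(0, 0), P(0, 0))

    def test_body_height(self):
        sag = _upright_sagittal()
        assert pg.body_height_px(sag) == pytest.approx(sag.MH.y - sag.LM.y)

    def test_body_height_translation_invariant(self):
        sag = _upright_sagittal()
        moved = pg.SagittalLandmarks(
            **{k: P(v.x + 50, v.y + 50) for k, v in sag.items()}
        )
        assert pg.body_height_px(moved) == pg.body_height_px(sag)

    def test_inverted_posture_rejected(self):
        with pytest.raises(InvalidPostureError):
            pg.SagittalLandmarks(
                MH=P(0, 0), MN=P(0, 10), C7=P(0, 8), FC=P(0, 5), L5=P(0, 2), LM=P(0, -9)
            )


def _upright_sagittal():
    return pg.SagittalLandmarks(
        MH=P(0, 180), MN=P(0, 160), C7=P(0, 150), FC=P(2, 100), L5=P(0, 80), LM=P(5, 0)
    )


def _upright_coronal():
    return pg.CoronalLandmarks(MH=P(0, 180), MN=P(0, 160), C7=P(0, 150), L5=P(0, 80))


class TestComputeFeatures:
    def test_straight_posture_is_all_zero(self):
        sag = pg.SagittalLandmarks(
            MH=P(0, 180), MN=P(0, 160), C7=P(0, 150), FC=P(0, 100), L5=P(0, 80), LM=P(0, 0)
        )
        cor = _upright_coronal()
        fv = pg.compute_features(sag, cor)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in fv.as_dict().values())

    def test_scale_invariance(self):
        sag, cor = _upright_sagittal(), _upright_coronal()
        fv1 = pg.compute_features(sag, cor)
        sag2 = pg.SagittalLandmarks(**{k: P(2 * v.x, 2 * v.y) for k, v in sag.items()})
        cor2 = pg.CoronalLandmarks(**{k: P(2 * v.x, 2 * v.y) for k, v in cor.items()})
        fv2 = pg.compute_features(sag2, cor2)
        for k in pg.FEATURE_NAMES:
            assert fv2.as_dict()[k] == pytest.approx(fv1.as_dict()[k], abs=1e-9)

    def test_translation_invariance(self):
        sag, cor = _upright_sagittal(), _upright_coronal()
        fv1 = pg.compute_features(sag, cor)
        sag2 = pg.SagittalLandmarks(**{k: P(v.x - 30, v.y + 70) for k, v in sag.items()})
        fv2 = pg.compute_features(sag2, cor)
        for k in pg.FEATURE_NAMES:
            assert fv2.as_dict()[k] == pytest.approx(fv1.as_dict()[k], abs=1e-9)

    def test_feature_vector_validates_ranges(self):
        with pytest.raises(InvalidInputError):
            pg.FeatureVector(200, 0, 0, 0, 0, 0, 0, 0)
        with pytest.raises(InvalidInputError):
            pg.FeatureVector(0, 0, 0, 0, 0, 0, -1, 0)


class TestSegmentation:
    def test_uniform_map_all_body(self):
        dm = pg.DepthMap(values=np.full((4, 5), 1000.0))
        mask = pg.segment_body(dm, pg.SegmentationParams(d_c=1000, thr=10))
        assert mask.all() and mask.shape == (4, 5)

    def test_boundary_is_strict(self):
        dm = pg.DepthMap(values=np.array([[1000.0, 1050.0]]))
        mask = pg.segment_body(dm, pg.SegmentationParams(d_c=1000, thr=50))
        assert mask.tolist() == [[True, False]]

    def test_2x2_example(self):
        dm = pg.DepthMap(values=np.array([[1000.0, 1400.0], [1010.0, 990.0]]))
        mask = pg.segment_body(dm, pg.SegmentationParams(d_c=1000, thr=50))
        assert mask.tolist() == [[True, False], [True, True]]

    def test_matches_per_pixel_oracle_on_random_maps(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = rng.uniform(0, 4000, size=(32, 32))
            d_c = float(rng.uniform(500, 3500))
            thr = float(rng.uniform(1, 800))
            mask = pg.segment_body(pg.DepthMap(values=vals), pg.SegmentationParams(d_c, thr))
            oracle = np.empty((32, 32), dtype=bool)
            for i in range(32):
                for j in range(32):
                    oracle[i, j] = abs(vals[i, j] - d_c) < thr
            assert np.array_equal(mask, oracle)

    def test_empty_and_invalid_maps_rejected(self):
        with pytest.raises(InvalidInputError):
            pg.DepthMap(values=np.empty((0, 3)))
        with pytest.raises(InvalidInputError):
            pg.SegmentationParams(d_c=100, thr=0)
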