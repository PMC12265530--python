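"""Displacement/speed/acceleration, tail angle and axial summaries."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import chisquare

from mirrorwell.errors import FormatError, GeometryError
from mirrorwell.geometry import WellGeometry, WorldPoint
from mirrorwell.kinematics import (
    axial_summary,
    compare_2d_3d,
    kinematics_from_track,
    reference_point,
    tail_angle,
)
from mirrorwell.skeleton3d import Skeleton3D
from mirrorwell.tracking_io import LANDMARKS


def head_skeleton(nostril, eye_left, eye_right, tail4) -> Skeleton3D:
    pts = {name: WorldPoint(0.0, 0.0, 0.0) for name in LANDMARKS}
    pts["nostril"] = WorldPoint(*nostril)
    pts["eye_left"] = WorldPoint(*eye_left)
    pts["eye_right"] = WorldPoint(*eye_right)
    pts["tail_4"] = WorldPoint(*tail4)
    return Skeleton3D(frame_index=0, landmarks=pts)


class TestReferencePoint:
    @pytest.mark.parametrize(
        "left, right, expected",
        [
            ((0, 0, 0), (2, 0, 0), (1, 0, 0)),
            ((1, 1, 1), (1, 1, 1), (1, 1, 1)),
            ((1, 2, 3), (3, 2, 1), (2, 2, 2)),
        ],
    )
    def test_eye_midpoint(self, left, right, expected):
        sk = head_skeleton((5, 5, 5), left, right, (0, 0, 0))
        assert reference_point(sk).as_array() == pytest.approx(expected)


class TestKinematicsFromTrack:
    def test_stationary_track_all_zero(self):
        refs = np.zeros((10, 3))
        tab = kinematics_from_track(refs, 20.0)
        assert np.nansum(tab.frames["displacement_mm"]) == 0.0
        assert tab.total_distance == 0.0 and tab.move_count == 0

    def test_three_four_five_steps(self):
        steps = np.array([0.3, 0.4, 0.0])
        refs = np.arange(11)[:, None] * steps
        tab = kinematics_from_track(refs, 20.0)
        d = tab.frames["displacement_mm"].to_numpy()
        assert np.isnan(d[0]) and d[1:] == pytest.approx(0.5)
        assert tab.frames["speed_mm_s"].to_numpy()[1:] == pytest.approx(10.0)
        acc = tab.frames["acceleration_mm_s2"].to_numpy()
        assert acc[2:] == pytest.approx(0.0)
        assert tab.total_distance == pytest.approx(5.0)

    def test_matches_brute_force_on_helix(self):
        t = np.linspace(0, 4 * math.pi, 200)
        refs = np.column_stack([2 * np.cos(t), 2 * np.sin(t), 0.1 * t])
        fps = 20.0
        tab = kinematics_from_track(refs, fps)
        # independent recomputation, frame by frame, from the coordinates
        for i in [1, 50, 120, 199]:
            d = math.dist(refs[i], refs[i - 1])
            assert tab.frames["displacement_mm"][i] == pytest.approx(d, rel=1e-12)
            assert tab.frames["speed_mm_s"][i] == pytest.approx(d * fps, rel=1e-12)
        for i in [2, 51, 121, 199]:
            dv = (
                math.dist(refs[i], refs[i - 1]) - math.dist(refs[i - 1], refs[i - 2])
            ) * fps
            assert tab.frames["acceleration_mm_s2"][i] == pytest.approx(
                dv * fps, rel=1e-9
            )
        assert tab.total_distance == pytest.approx(
            sum(math.dist(refs[i], refs[i - 1]) for i in range(1, 200)), rel=1e-12
        )

    def test_move_count_requires_sustained_speed(self):
        refs = np.zeros((12, 3))
        refs[3:6, 0] = [1.0, 2.0, 3.0]  # 3 fast frames then stop
        refs[9, 0] = 10.0  # single-frame spike (and one on return)
        tab = kinematics_from_track(refs, 20.0, move_threshold=2.0, min_move_frames=2)
        assert tab.move_count == 2  # the run and the 2-frame spike out/back

    def test_gap_breaks_displacement_chain(self):
        refs = np.zeros((6, 3))
        refs[:, 0] = [0, 1, 2, 10, 11, 12]
        idx = np.array([0, 1, 2, 10, 11, 12])  # frames 3..9 were QC-dropped
        tab = kinematics_from_track(refs, 20.0, frame_index=idx)
        d = tab.frames["displacement_mm"].to_numpy()
        assert np.isnan(d[3])  # the 8 mm jump is not bridged
        assert tab.total_distance == pytest.approx(4.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(FormatError):
            kinematics_from_track(np.zeros((2, 3)), 20.0)


class TestTailAngle:
    def test_straight_body_zero(self):
        sk = head_skeleton((0, 0, 0), (1, 0.2, 0), (1, -0.2, 0), (3, 0, 0))
        assert tail_angle(sk) == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_tail(self):
        sk = head_skeleton((0, 0, 0), (1, 0, 0), (1, 0, 0), (0, 1, 0))
        assert tail_angle(sk) == pytest.approx(90.0)

    def test_vertical_bend_invisible_in_2d(self):
        sk = head_skeleton((0, 0, 0), (1, 0, 0), (1, 0, 0), (1, 0, 1))
        assert tail_angle(sk, mode="2D") == pytest.approx(0.0, abs=1e-9)
        assert tail_angle(sk, mode="3D") == pytest.approx(45.0)

    def test_rigid_rotation_invariance_in_3d(self):
        sk = head_skeleton((0, 0, 0), (1, 0.3, 0.1), (1, -0.1, 0.2), (2.5, 1.0, 0.8))
        base = tail_angle(sk)
        for seed in range(5):
            R = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            pts = {
                n: WorldPoint(*(R @ p.as_array())) for n, p in sk.landmarks.items()
            }
            rotated = Skeleton3D(frame_index=0, landmarks=pts)
            assert abs(tail_angle(rotated) - base) < 1e-9

    def test_zero_length_vector_rejected(self):
        sk = head_skeleton((0, 0, 0), (0, 0, 0), (0, 0, 0), (1, 0, 0))
        with pytest.raises(GeometryError):
            tail_angle(sk)


class TestCompare2d3d:
    def test_planar_track_identical(self):
        rng = np.random.default_rng(7)
        refs = np.column_stack([rng.uniform(-3, 3, 50), rng.uniform(-3, 3, 50), np.full(50, 6.0)])
        t2 = kinematics_from_track(refs, 20.0, "2D")
        t3 = kinematics_from_track(refs, 20.0, "3D")
        out = compare_2d_3d(t2, t3)
        assert out["total_distance_gap"] == pytest.approx(0.0, abs=1e-12)

    def test_projection_inequality_per_frame(self):
        rng = np.random.default_rng(8)
        refs = np.cumsum(rng.normal(0, 0.2, size=(100, 3)), axis=0)
        t2 = kinematics_from_track(refs, 20.0, "2D")
        t3 = kinematics_from_track(refs, 20.0, "3D")
        diff = compare_2d_3d(t2, t3)["per_frame"]["displacement_diff_mm"].to_numpy()
        assert np.all(diff[1:] >= -1e-12)

    def test_vertical_gap_matches_brute_force(self):
        n = 60
        refs = np.zeros((n, 3))
        refs[:, 0] = np.arange(n) * 0.1
        refs[:, 2] = np.sin(np.arange(n) * 0.5)  # known vertical component
        t2 = kinematics_from_track(refs, 20.0, "2D")
        t3 = kinematics_from_track(refs, 20.0, "3D")
        gap = compare_2d_3d(t2, t3)["total_distance_gap"]
        brute = sum(
            math.dist(refs[i], refs[i - 1]) - math.dist(refs[i, :2], refs[i - 1, :2])
            for i in range(1, n)
        )
        assert gap == pytest.approx(brute, rel=1e-12)

    def test_frame_mismatch_rejected(self):
        t2 = kinematics_from_track(np.zeros((5, 3)), 20.0, "2D")
        t3 = kinematics_from_track(np.zeros((6, 3)), 20.0, "3D")
        with pytest.raises(FormatError):
            compare_2d_3d(t2, t3)


class TestAxialSummary:
    def test_constant_depth(self, well_geom):
        refs = np.tile([0.5, -0.5, 3.0], (40, 1))
        out = axial_summary(refs, 20.0, well_geom, bin_size=1.0)
        assert np.all(out.depth_sd_mm[~np.isnan(out.depth_sd_mm)] == 0.0)
        assert (out.occupancy > 0).sum() == 1

    def test_counts_conserved(self, well_geom):
        rng = np.random.default_rng(9)
        refs = np.column_stack(
            [rng.uniform(-4, 4, 500), rng.uniform(-4, 4, 500), rng.uniform(0, 12, 500)]
        )
        out = axial_summary(refs, 20.0, well_geom, bin_size=2.0)
        assert out.occupancy.sum() == 500

    def test_uniform_depth_distribution(self, well_geom):
        rng = np.random.default_rng(10)
        n = 10_000
        refs = np.column_stack(
            [np.zeros(n), np.zeros(n), rng.uniform(0, 12, n)]
        )
        out = axial_summary(refs, 20.0, well_geom, bin_size=1.0)
        z_counts = out.occupancy.sum(axis=(0, 1))
        _, p = chisquare(z_counts)
        assert p > 1e-3  # uniform sampling should not be wildly rejected
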