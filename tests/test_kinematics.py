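"""Tail angular kinematics and COM linear kinematics."""

from __future__ import annotations

import numpy as np
import pytest

from escapekin import (
    NoMovementError,
    OnsetConfig,
    SmoothingConfig,
    angular_velocity,
    body_length,
    central_difference,
    com_kinematics,
    detect_onset,
    segment_angles,
    smooth_series,
    standardize_sign,
    tail_curvature,
)
from escapekin.pose_io import TrialRecording

from conftest import arc_pose, recording_from_pose, straight_recording


class TestSegmentAngles:
    def test_straight_body_gives_zero_angles(self):
        rec = straight_recording()
        ang = segment_angles(rec)
        np.testing.assert_allclose(ang, 0.0, atol=1e-10)

    @pytest.mark.parametrize("bend", [80.0, -60.0, 140.0])
    def test_uniform_arc_splits_evenly(self, bend):
        """A tail bent as a uniform arc of B degrees gives B/4 per joint."""
        rec = recording_from_pose(arc_pose(bend))
        ang = segment_angles(rec)
        np.testing.assert_allclose(ang, bend / 4.0, atol=1e-9)
        np.testing.assert_allclose(tail_curvature(ang), bend, atol=1e-8)

    def test_rigid_rotation_leaves_relative_angles_unchanged(self):
        pose = arc_pose(50.0)
        theta = np.radians(30.0)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        rec_a = recording_from_pose(pose)
        rec_b = recording_from_pose(pose @ R.T + np.array([3.0, -2.0]))
        np.testing.assert_allclose(
            segment_angles(rec_a), segment_angles(rec_b), atol=1e-9
        )

    def test_straight_body_rotating_stays_zero(self):
        n = 20
        xy = np.empty((n, 7, 2))
        offsets = np.concatenate([[0.0], np.cumsum([0.5, 0.5, 1, 1, 1, 1])])
        for f in range(n):
            th = np.radians(30.0) * f / (n - 1)
            xy[f] = np.outer(offsets, [np.cos(th), np.sin(th)])
        rec = TrialRecording(xy=xy, likelihood=np.ones((n, 7)))
        np.testing.assert_allclose(segment_angles(rec), 0.0, atol=1e-9)

    def test_kappa_telescopes_to_tip_orientation(self):
        """Sum of relative angles equals the tail-tip direction vs the trunk
        axis for arbitrary synthetic poses."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            joints = rng.uniform(-40, 40, size=4)
            pts = [np.array([0.0, 0.0])]
            ang = 0.0
            for L, da in zip([0.5, 0.5, 1, 1, 1, 1], [0, 0, *joints]):
                ang += np.radians(da)
                pts.append(pts[-1] + L * np.array([np.cos(ang), np.sin(ang)]))
            rec = recording_from_pose(np.asarray(pts), n_frames=1)
            # bypass unwrap concerns: single frame
            kappa = tail_curvature(segment_angles(rec))[0]
            assert kappa == pytest.approx(joints.sum(), abs=1e-8)


class TestSmoothing:
    def test_constant_is_fixed_point(self):
        y = np.full(50, 3.25)
        np.testing.assert_allclose(smooth_series(y, 0.3), y, atol=1e-12)

    def test_reproduces_line_exactly(self):
        t = np.arange(60, dtype=float)
        y = 2.0 * t + 1.0
        np.testing.assert_allclose(smooth_series(y, 0.10), y, atol=1e-8)

    def test_reduces_noise_on_sinusoid(self):
        rng = np.random.default_rng(42)
        t = np.arange(200)
        clean = 10 * np.sin(2 * np.pi * t / 60)
        noise = rng.normal(0, 1.0, t.size)
        smoothed = smooth_series(clean + noise, 0.10)
        assert np.std(smoothed - clean) < np.std(noise)

    @pytest.mark.parametrize("span", [0.0, -0.5, 1.5])
    def test_invalid_span_rejected(self, span):
        with pytest.raises(ValueError):
            smooth_series(np.arange(20.0), span)


class TestSignStandardization:
    def test_first_major_negative_bend_flips_series(self):
        t = np.linspace(0, 60, 61)
        kappa = -60.0 * np.sin(2 * np.pi * t / 40)
        std, sign, ok = standardize_sign(kappa)
        assert ok and sign == -1.0
        assert std[np.argmax(np.abs(std[:20]))] > 0

    def test_counter_bend_does_not_set_the_sign(self):
        """A small opposite dip before the C-start is ignored."""
        t = np.arange(80.0)
        kappa = np.zeros(80)
        kappa[5:15] = -8.0 * np.sin(np.pi * (t[5:15] - 5) / 10)   # small dip
        kappa[15:45] = -60.0 * np.sin(np.pi * (t[15:45] - 15) / 30) * -1  # +C-start...
        kappa[15:45] = 60.0 * np.sin(np.pi * (t[15:45] - 15) / 30)
        std, sign, ok = standardize_sign(kappa)
        assert sign == 1.0  # defined by the +60 bend, not the -8 dip

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        kappa = rng.normal(0, 20, 100)
        once, s1, _ = standardize_sign(kappa)
        twice, s2, _ = standardize_sign(once)
        np.testing.assert_array_equal(once * s2, twice)
        assert s2 == 1.0

    def test_all_zero_flagged_unstandardized(self):
        std, sign, ok = standardize_sign(np.zeros(30))
        assert not ok and sign == 1.0


class TestDerivatives:
    def test_exact_on_linear(self):
        t = np.arange(40.0)
        np.testing.assert_allclose(angular_velocity(3.0 * t, 1.0), 3.0, atol=1e-12)

    def test_central_difference_exact_on_quadratic_interior(self):
        t = np.arange(30.0)
        d = central_difference(t**2, 1.0)
        np.testing.assert_allclose(d[1:-1], 2 * t[1:-1], atol=1e-10)

    def test_sampled_sinusoid_matches_discrete_closed_form(self):
        """The central difference of sin(2 pi f t) has amplitude
        2 pi f * sinc-like factor sin(2 pi f dt) / (2 pi f dt)."""
        f, dt = 0.02, 1.0
        t = np.arange(0, 500, dt)
        d = central_difference(np.sin(2 * np.pi * f * t), dt)
        expected = 2 * np.pi * f * np.sin(2 * np.pi * f * dt) / (2 * np.pi * f * dt)
        assert np.max(np.abs(d[1:-1])) == pytest.approx(expected, rel=1e-4)


class TestOnset:
    def test_onset_on_growing_curvature(self):
        kappa = np.zeros(30)
        kappa[10:] = [1, 3, 8, 15, 25, 35, 45, 52, 58, 60, 61, 61, 61, 61,
                      61, 61, 61, 61, 61, 61]
        # brute-force application of the rule: first frame over the floor
        # whose growth is confirmed on the next 2 frames
        assert detect_onset(kappa, stimulus_frame=9) == 10

    def test_flat_series_raises(self):
        with pytest.raises(NoMovementError):
            detect_onset(np.zeros(50), stimulus_frame=10)

    def test_single_frame_blip_is_not_onset(self):
        kappa = np.zeros(40)
        kappa[15] = 5.0  # one-frame spike, then flat
        with pytest.raises(NoMovementError):
            detect_onset(kappa, stimulus_frame=10)

    def test_growth_below_floor_ignored(self):
        kappa = np.zeros(40)
        kappa[12:] = 0.3  # grows from 0 but stays under the 0.5 deg floor
        with pytest.raises(NoMovementError):
            detect_onset(kappa, stimulus_frame=10)


class TestBodyLength:
    def test_sum_of_segments(self):
        rec = straight_recording(seg_mm=(0.5, 0.7, 0.7, 0.7, 0.7, 0.7))
        assert body_length(rec) == pytest.approx(4.0, abs=1e-12)

    def test_invariant_under_rotation(self):
        a = straight_recording(heading_rad=0.0)
        b = straight_recording(heading_rad=1.1)
        assert body_length(a) == pytest.approx(body_length(b), abs=1e-12)

    def test_jittered_estimate_near_truth(self):
        """BL from 10 jittered pre-stimulus frames stays within the
        propagated-noise envelope of the true 4 mm."""
        rng = np.random.default_rng(5)
        rec = straight_recording()
        sd = 0.064
        rec.xy[:10] += rng.normal(0, sd, size=(10, 7, 2))
        # each of 6 lengths gains noise ~ sd*sqrt(2)(worst case, correlated
        # shared endpoints partially cancel); averaged over 10 frames
        tol = 3 * sd * np.sqrt(2) * 6 / np.sqrt(10)
        assert body_length(rec) == pytest.approx(4.0, abs=tol)

    def test_no_premovement_frames_errors(self):
        rec = straight_recording()
        with pytest.raises(ValueError):
            body_length(rec, onset_frame=0)


class TestCOMKinematics:
    def test_straight_constant_speed_path(self):
        """0.2 mm/frame on a 4 mm larva at 1000 fps: 3 BL and 50 BL/s
        after 60 ms, with distance == displacement throughout."""
        rec = straight_recording(n_frames=80, step_mm=0.2)
        com = com_kinematics(rec, onset_frame=10, bl_mm=4.0)
        assert com.distance[60] == pytest.approx(3.0, abs=1e-9)
        np.testing.assert_allclose(com.distance, com.displacement, atol=1e-9)
        np.testing.assert_allclose(com.speed_raw[1:-1], 50.0, atol=1e-6)
        np.testing.assert_allclose(com.speed[5:-5], 50.0, atol=1e-6)

    def test_semicircle_distance_vs_displacement(self):
        """Half-circle path: distance/displacement -> pi/2."""
        n = 101
        th = np.linspace(0, np.pi, n)
        r = 2.0
        xy = np.zeros((n + 10, 7, 2))
        base = straight_recording(n_frames=1).xy[0]
        xy[:] = base
        s2 = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
        xy[10:, :, :] = base + (s2 - s2[0])[:, None, :]
        rec = TrialRecording(xy=xy, likelihood=np.ones((n + 10, 7)))
        com = com_kinematics(rec, onset_frame=10, bl_mm=4.0)
        assert com.distance[-1] / com.displacement[-1] == pytest.approx(
            np.pi / 2, rel=1e-3
        )

    def test_stationary_com_is_all_zero(self):
        rec = straight_recording(n_frames=80)
        com = com_kinematics(rec, onset_frame=10, bl_mm=4.0)
        for series in (com.distance, com.displacement, com.speed_raw,
                       com.velocity, com.acceleration):
            np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_distance_dominates_displacement(self, wt_trial_clean):
        from escapekin import compute_curvature_series

        curv = compute_curvature_series(wt_trial_clean)
        com = com_kinematics(wt_trial_clean, curv.onset_frame)
        assert np.all(com.distance - com.displacement >= -1e-9)
        assert np.all(np.diff(com.distance) >= 0)
        assert com.distance[0] == 0 and com.displacement[0] == 0


class TestInvariances:
    def test_rigid_motion_invariance_of_kinematics(self, wt_trial_clean):
        """Translating and rotating every keypoint identically leaves
        curvature, distance, displacement and speed unchanged."""
        from escapekin import compute_curvature_series

        rec = wt_trial_clean
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = TrialRecording(
            xy=rec.xy @ R.T + np.array([7.0, -3.0]),
            likelihood=rec.likelihood,
            fps=rec.fps, px_per_mm=rec.px_per_mm,
            pre_stimulus_frames=rec.pre_stimulus_frames, meta=rec.meta,
        )
        ca = compute_curvature_series(rec)
        cb = compute_curvature_series(moved)
        np.testing.assert_allclose(ca.kappa, cb.kappa, atol=1e-8)
        va = com_kinematics(rec, ca.onset_frame)
        vb = com_kinematics(moved, cb.onset_frame)
        np.testing.assert_allclose(va.distance, vb.distance, atol=1e-9)
        np.testing.assert_allclose(va.displacement, vb.displacement, atol=1e-9)
        np.testing.assert_allclose(va.speed_raw, vb.speed_raw, atol=1e-6)

    def test_calibration_cancels_in_bl_units(self, wt_trial_clean):
        """Doubling px_per_mm (half-size mm coordinates) leaves every
        BL-normalized output unchanged."""
        from escapekin import compute_curvature_series

        rec = wt_trial_clean
        half = TrialRecording(
            xy=rec.xy / 2.0, likelihood=rec.likelihood, fps=rec.fps,
            px_per_mm=rec.px_per_mm * 2, pre_stimulus_frames=rec.pre_stimulus_frames,
            meta=rec.meta,
        )
        ca, cb = compute_curvature_series(rec), compute_curvature_series(half)
        np.testing.assert_allclose(ca.kappa, cb.kappa, atol=1e-8)
        va = com_kinematics(rec, ca.onset_frame)
        vb = com_kinematics(half, cb.onset_frame)
        np.testing.assert_allclose(va.distance, vb.distance, atol=1e-9)
        np.testing.assert_allclose(va.speed, vb.speed, atol=1e-6)
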