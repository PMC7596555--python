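"""NIC computation, blink handling, filtering and robust detrending."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pursuitspect import synthetic as syn
from pursuitspect.errors import (
    DegenerateGeometryError,
    EmptySignalError,
    InvalidParameterError,
)
from pursuitspect.trajectory import (
    GazeTrajectory,
    Mask,
    compute_nic,
    detect_blinks,
    detrend_repeated_median,
    eye_aspect_ratio,
    interpolate_blinks,
    lowpass,
    select_trial_segments,
)


def make_track(n=20, iris_x=120.0, fps=240.0):
    """Minimal landmark track with corners at (100,50) and (140,50)."""
    geom = syn.EyeGeometry(corner_left_px=(100, 50), corner_right_px=(140, 50))
    track = syn.render_landmarks(np.zeros(n), geom, syn.SimProfile(seed=0), fps)
    track.frames["iris_left_x"] = iris_x
    return track


def make_traj(x, fps=240.0, mask=None):
    x = np.asarray(x, float)
    mask = np.zeros(len(x), np.int8) if mask is None else np.asarray(mask, np.int8)
    t = np.arange(len(x)) / fps
    return GazeTrajectory(x, x.copy(), fps, mask, t)


class TestComputeNic:
    def test_iris_at_midpoint_gives_zero(self):
        traj = compute_nic(make_track(iris_x=120.0), scale=False)
        assert np.allclose(traj.x, 0.0) and np.allclose(traj.y, 0.0)

    def test_scaled_offset_is_fraction_of_eye_width(self):
        traj = compute_nic(make_track(iris_x=130.0), scale=True)
        assert np.allclose(traj.x, 10.0 / 40.0)

    def test_undetected_frames_are_masked_missing(self):
        track = make_track(n=10)
        track.frames.loc[3, "detected"] = False
        traj = compute_nic(track)
        assert traj.mask[3] == Mask.MISSING
        assert np.isnan(traj.x[3])
        assert (traj.mask[:3] == Mask.VALID).all()

    def test_all_undetected_raises(self):
        track = make_track(n=5)
        track.frames["detected"] = False
        with pytest.raises(EmptySignalError):
            compute_nic(track)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_translation_invariance(self, dx, dy):
        track = make_track(n=4, iris_x=128.0)
        moved = track.copy()
        for col in moved.frames.columns:
            if col.endswith("_x"):
                moved.frames[col] = moved.frames[col] + dx
            elif col.endswith("_y"):
                moved.frames[col] = moved.frames[col] + dy
        a, b = compute_nic(track), compute_nic(moved)
        np.testing.assert_allclose(a.x, b.x, atol=1e-9)
        np.testing.assert_allclose(a.y, b.y, atol=1e-9)

    @given(st.floats(0.1, 10.0))
    def test_scaled_nic_invariant_to_uniform_scaling(self, c):
        track = make_track(n=4, iris_x=128.0)
        scaled = track.copy()
        for col in scaled.frames.columns:
            if col.endswith(("_x", "_y")):
                scaled.frames[col] = scaled.frames[col] * c
        a, b = compute_nic(track, scale=True), compute_nic(scaled, scale=True)
        np.testing.assert_allclose(a.x, b.x, atol=1e-9)


class TestEyeAspectRatio:
    def test_hand_computed_example(self):
        lm = np.array([(0, 0), (1, 1), (3, 1), (4, 0), (3, -1), (1, -1)], float)
        assert eye_aspect_ratio(lm) == pytest.approx(0.5)

    def test_closed_eye_is_zero(self):
        lm = np.array([(0, 0), (1, 0), (3, 0), (4, 0), (3, 0), (1, 0)], float)
        assert eye_aspect_ratio(lm) == 0.0

    def test_scale_invariance(self):
        lm = np.array([(0, 0), (1, 1), (3, 1), (4, 0), (3, -1), (1, -1)], float)
        assert eye_aspect_ratio(2.0 * lm) == pytest.approx(eye_aspect_ratio(lm))

    def test_coincident_corners_rejected(self):
        lm = np.zeros((6, 2))
        with pytest.raises(DegenerateGeometryError):
            eye_aspect_ratio(lm)


class TestDetectBlinks:
    def test_open_eyes_give_empty_mask(self):
        track = make_track(n=100)
        mask, intervals = detect_blinks(track, ear_threshold=0.2)
        assert not mask.any() and intervals == []

    def test_zero_threshold_never_fires(self):
        geom = syn.EyeGeometry()
        track = syn.render_landmarks(np.zeros(500), geom, syn.SimProfile(seed=0))
        track, _ = syn.inject_blinks(track, syn.SimProfile(blink_rate_hz=0.5, seed=1), geom)
        mask, _ = detect_blinks(track, ear_threshold=0.0)
        assert not mask.any()

    def test_injected_blinks_are_recovered(self):
        geom = syn.EyeGeometry()
        n_blinks = 0
        for seed in range(3):
            track = syn.render_landmarks(np.zeros(240 * 15), geom, syn.SimProfile(seed=seed))
            track, truth = syn.inject_blinks(
                track, syn.SimProfile(blink_rate_hz=0.25, seed=seed), geom
            )
            mask, found = detect_blinks(track)
            for a, b in truth:
                assert mask[a:b].any(), f"blink {a}-{b} missed (seed {seed})"
            assert len(found) == len(truth)
            n_blinks += len(truth)
        assert n_blinks >= 3


class TestInterpolateBlinks:
    def test_no_blinks_leaves_trajectory_unchanged(self):
        traj = make_traj(np.sin(np.arange(100) / 10))
        out = interpolate_blinks(traj, np.zeros(100, bool))
        assert out is traj

    def test_cubic_gap_reproduces_cubic_signal(self):
        t = np.arange(200) / 240
        traj = make_traj((t * 10) ** 3)
        blink = np.zeros(200, bool)
        blink[90:100] = True
        out = interpolate_blinks(traj, blink)
        np.testing.assert_allclose(out.x[90:100], (t[90:100] * 10) ** 3, atol=1e-6)

    def test_interpolated_frames_never_revert_to_valid(self):
        traj = make_traj(np.sin(np.arange(100) / 7.0))
        blink = np.zeros(100, bool)
        blink[10:20] = True
        out = interpolate_blinks(traj, blink)
        assert (out.mask[10:20] == Mask.BLINK_INTERPOLATED).all()
        assert np.isfinite(out.x[10:20]).all()

    def test_missing_frames_are_bridged_and_stay_flagged(self):
        mask = np.zeros(100, np.int8)
        mask[50:55] = Mask.MISSING
        x = np.sin(np.arange(100) / 7.0)
        x[50:55] = np.nan
        traj = make_traj(x, mask=mask)
        out = interpolate_blinks(traj, np.zeros(100, bool))
        assert np.isfinite(out.x).all()
        assert (out.mask[50:55] == Mask.BLINK_INTERPOLATED).all()

    def test_boundary_gap_held_not_extrapolated(self):
        x = np.sin(np.arange(100) / 7.0)
        traj = make_traj(x)
        blink = np.zeros(100, bool)
        blink[:10] = True
        out = interpolate_blinks(traj, blink)
        assert np.allclose(out.x[:10], out.x[10])


class TestLowpass:
    @pytest.mark.parametrize(
        "freq,bound,side",
        [(2.0, 0.99, "above"), (20.0, 0.1, "below")],
    )
    def test_passband_and_stopband_amplitudes(self, freq, bound, side):
        fps = 240.0
        t = np.arange(int(10 * fps)) / fps
        traj = make_traj(np.sin(2 * np.pi * freq * t), fps)
        out = lowpass(traj, 8.0)
        amp = np.abs(out.x[int(fps) : -int(fps)]).max()
        if side == "above":
            assert amp > bound
        else:
            assert amp < bound

    def test_constant_signal_unchanged(self):
        traj = make_traj(np.full(1000, 3.7))
        out = lowpass(traj, 8.0)
        np.testing.assert_allclose(out.x, 3.7, atol=1e-9)

    def test_undersampled_signal_rejected(self):
        traj = make_traj(np.zeros(100), fps=10.0)
        with pytest.raises(InvalidParameterError):
            lowpass(traj, 8.0)

    def test_masks_preserved(self):
        mask = np.zeros(500, np.int8)
        mask[100:110] = Mask.BLINK_INTERPOLATED
        traj = make_traj(np.sin(np.arange(500) / 9.0), mask=mask)
        out = lowpass(traj, 8.0)
        assert np.array_equal(out.mask, mask)


class TestDetrendRepeatedMedian:
    def test_affine_trend_annihilated(self):
        fps = 60.0
        t = np.arange(int(10 * fps)) / fps
        traj = make_traj(3.0 + 0.7 * t, fps)
        out = detrend_repeated_median(traj, 1.0)
        assert np.abs(out.x).max() < 1e-9

    def test_sine_on_line_recovered_within_5pct(self):
        fps = 60.0
        t = np.arange(int(15 * fps)) / fps
        sine = np.sin(2 * np.pi * 2.0 * t)
        traj = make_traj(2.0 - 0.5 * t + sine, fps)
        out = detrend_repeated_median(traj, 1.0)
        core = slice(int(2 * fps), -int(2 * fps))
        amp = np.percentile(np.abs(out.x[core]), 95)
        assert abs(amp - 1.0) < 0.05

    def test_robust_to_30pct_outliers(self):
        fps = 60.0
        t = np.arange(int(6 * fps)) / fps
        line = 1.0 + 2.0 * t
        x = line.copy()
        rng = np.random.default_rng(0)
        out_idx = rng.choice(len(x), size=int(0.3 * len(x)), replace=False)
        x[out_idx] += rng.normal(0, 50, len(out_idx))
        res = detrend_repeated_median(make_traj(x, fps), 1.0)
        trend = x - res.x
        clean_idx = np.setdiff1d(np.arange(len(x)), out_idx)
        rel_err = np.abs(trend[clean_idx] - line[clean_idx]) / np.ptp(line)
        assert np.median(rel_err) < 0.1

    def test_window_shorter_than_5_samples_rejected(self):
        with pytest.raises(InvalidParameterError):
            detrend_repeated_median(make_traj(np.zeros(100), fps=60.0), 0.01)


class TestSelectTrialSegments:
    def test_t1_schedule_frame_count(self):
        fps = 240.0
        dur = 2 * (32 / 11 + 5.0)  # ~15.8 s
        n = int(np.floor(dur * fps)) + 1
        traj = make_traj(np.zeros(n), fps)
        segs = select_trial_segments(traj, [{"trial_id": "T1", "onset_s": 0.0, "offset_s": dur}])
        (tid, (a, b)) = segs[0]
        assert tid == "T1"
        assert abs((b - a) - 3796) <= 2

    def test_empty_schedule(self):
        traj = make_traj(np.zeros(100))
        assert select_trial_segments(traj, []) == []

    def test_two_trials_are_disjoint_and_ordered(self):
        traj = make_traj(np.zeros(1000), fps=100.0)
        sched = [
            {"trial_id": "T1", "onset_s": 0.0, "offset_s": 4.0},
            {"trial_id": "T2", "onset_s": 5.0, "offset_s": 9.0},
        ]
        segs = select_trial_segments(traj, sched)
        assert [s[0] for s in segs] == ["T1", "T2"]
        assert segs[0][1][1] <= segs[1][1][0]

    def test_out_of_range_schedule_clipped(self):
        traj = make_traj(np.zeros(100), fps=100.0)
        segs = select_trial_segments(traj, [{"trial_id": "T1", "onset_s": 0.5, "offset_s": 10.0}])
        assert segs[0][1] == (50, 100)
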