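"""Gap-aware series assembly, the mirrored spectral low-pass, trends,
gaze classification and frame rejection."""

import numpy as np
import pytest

from oculid.config import PipelineConfig
from oculid.landmarks import EyeHexagon, FixtureLandmarkProvider, extract_eye_hexagons
from oculid.synthetic import SyntheticEyeSpec, render_frame
from oculid.timeseries import (
    assemble_series,
    classify_gaze,
    detect_exercise_window,
    filter_series,
    fit_trend,
    reject_frames,
)


# --- assembly --------------------------------------------------------------


def test_linear_interpolation_is_exact():
    t = np.array([0.0, 0.5])
    v = np.array([1.0, 2.0])
    s = assemble_series(t, v, grid_timestamps=np.array([0.0, 0.25, 0.5]))
    assert s.interpolated[1] == pytest.approx(1.5)
    assert s.gaps == []


def test_gaps_longer_than_one_second_never_interpolated():
    t = np.array([9.0, 10.0, 12.0, 13.0])
    v = np.array([1.0, 1.0, 2.0, 2.0])
    grid = np.arange(9.0, 13.01, 0.25)
    s = assemble_series(t, v, grid_timestamps=grid)
    assert s.gaps == [(10.0, 12.0)]
    hole = (grid > 10.0) & (grid < 12.0)
    assert np.isnan(s.interpolated[hole]).all()
    assert np.isfinite(s.interpolated[~hole]).all()


def test_no_extrapolation_outside_support():
    t = np.array([1.0, 2.0])
    v = np.array([5.0, 6.0])
    grid = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
    s = assemble_series(t, v, grid_timestamps=grid)
    assert np.isnan(s.interpolated[0]) and np.isnan(s.interpolated[-1])


# --- filtering -------------------------------------------------------------


def grid_series(values, fps=30.0):
    t = np.arange(len(values)) / fps
    return assemble_series(t, values, grid_timestamps=t)


def test_filter_preserves_constant():
    s = grid_series(np.full(300, 0.7))
    out = filter_series(s)
    assert np.allclose(out, 0.7, atol=1e-9)


def test_filter_passes_linear_ramp_within_one_percent():
    t = np.arange(1800) / 30.0
    ramp = 1.0 - 0.15 * t / 60.0
    s = grid_series(ramp)
    out = filter_series(s)
    assert np.max(np.abs(out - ramp)) <= 0.01 * (ramp.max() - ramp.min()) + 1e-6


def test_filter_attenuates_5hz_sinusoid_20x_keeps_ramp():
    t = np.arange(1800) / 30.0
    ramp = 1.0 - 0.15 * t / 60.0
    wig = 0.2 * np.sin(2 * np.pi * 5.0 * t)
    s = grid_series(ramp + wig)
    out = filter_series(s)
    resid = out - ramp
    interior = slice(30, -30)  # mirror ends carry the residual leakage
    assert np.abs(resid[interior]).max() <= 0.2 / 20.0
    assert np.abs(resid).mean() <= 0.2 / 40.0


def test_filter_is_idempotent_and_mean_preserving():
    rng = np.random.default_rng(0)
    t = np.arange(900) / 30.0
    v = 0.5 + 0.05 * np.sin(2 * np.pi * 0.2 * t) + rng.normal(0, 0.02, 900)
    s = grid_series(v)
    once = filter_series(s).copy()
    s2 = assemble_series(t, once, grid_timestamps=t)
    twice = filter_series(s2)
    scale = once.max() - once.min()
    assert np.abs(twice - once).max() <= 0.01 * scale
    assert abs(once.mean() - v.mean()) <= 0.001 * abs(v.mean())


def test_filter_conserves_gaps():
    t = np.concatenate([np.arange(0, 10, 1 / 30), np.arange(12, 22, 1 / 30)])
    v = np.sin(t)
    s = assemble_series(t, v, grid_timestamps=t)
    assert len(s.gaps) == 1
    out = filter_series(s)
    nan_before = np.isnan(s.interpolated)
    assert np.array_equal(np.isnan(out), nan_before)
    assert s.gaps == [(pytest.approx(t[299]), pytest.approx(12.0))]


def test_short_segment_passes_unfiltered_with_flag():
    s = grid_series(np.sin(np.arange(60) / 30.0 * 40))  # 2 s segment
    out = filter_series(s)
    assert np.allclose(out, s.interpolated)
    assert "unfiltered_segment" in s.flags


# --- trend -----------------------------------------------------------------


def test_trend_recovers_exact_line():
    t = np.arange(0, 61.0, 0.5)
    v = 1.0 - 0.15 * (t / t[-1])
    s = assemble_series(t, v, grid_timestamps=t)
    filter_series(s)
    intercept, slope = fit_trend(s)
    assert slope == pytest.approx(-0.15, abs=0.002)
    assert intercept == pytest.approx(1.0, abs=0.002)


def test_trend_zero_for_constant():
    t = np.arange(0, 30.0, 0.5)
    s = assemble_series(t, np.full_like(t, 0.4), grid_timestamps=t)
    assert fit_trend(s)[1] == pytest.approx(0.0, abs=1e-9)


def test_trend_unavailable_with_insufficient_span():
    t = np.arange(0, 61.0, 0.5)
    v = np.where(t < 20, 1.0, np.nan)  # samples cover only a third
    ok = np.isfinite(v)
    s = assemble_series(t[ok], v[ok], grid_timestamps=t)
    assert fit_trend(s) is None


# --- gaze classification and exercise window -------------------------------


@pytest.mark.parametrize("gaze", ["up", "left", "right", "primary"])
def test_gaze_classified_from_scleral_layout(gaze):
    spec = SyntheticEyeSpec(gaze=gaze, noise_sigma=0.02, seed=4)
    img, truth = render_frame(spec, 0.0)
    for eye in truth.eyes:
        label = classify_gaze(img, EyeHexagon(eye.side, eye.hexagon), seed=1)
        assert label == gaze


def test_window_detected_on_scheduled_clip():
    """3 s primary-gaze flanks around a 24 s up-gaze span."""
    fps = 10.0
    t = np.arange(0, 30.0, 1 / fps)
    labels = np.where((t >= 3.0) & (t < 27.0), "up", "primary").tolist()
    win = detect_exercise_window(labels, list(labels), t, "ptosis_up")
    assert win is not None
    assert win.start == pytest.approx(3.0, abs=1.0)
    assert win.end == pytest.approx(27.0, abs=1.0)
    assert win.atypical  # 24 s is shorter than a nominal exercise


def test_window_unavailable_on_primary_gaze():
    t = np.arange(0, 30.0, 0.1)
    labels = ["primary"] * len(t)
    assert detect_exercise_window(labels, labels, t, "ptosis_up") is None


def test_window_requires_consistent_eyes():
    t = np.arange(0, 30.0, 0.1)
    up = ["up"] * len(t)
    down = ["primary"] * len(t)
    assert detect_exercise_window(up, down, t, "ptosis_up") is None


# --- rejection -------------------------------------------------------------


def _landmark_track(spec, n, fps):
    provider = FixtureLandmarkProvider(spec)
    sets, hexes = [], []
    for i in range(n):
        lm = provider(None, frame_index=i, timestamp=i / fps)
        sets.append(lm)
        hexes.append(extract_eye_hexagons(lm))
    return sets, hexes


def test_clean_static_sequence_has_zero_rejections():
    spec = SyntheticEyeSpec(noise_sigma=0.0)
    sets, hexes = _landmark_track(spec, 20, 10.0)
    reasons = reject_frames(sets, hexes, [None] * 20, [], np.arange(20) / 10.0)
    assert reasons == [""] * 20


def test_blink_frames_rejected_with_one_frame_margin():
    spec = SyntheticEyeSpec(noise_sigma=0.0)
    n, fps = 30, 10.0
    sets, hexes = _landmark_track(spec, n, fps)
    t = np.arange(n) / fps
    reasons = reject_frames(sets, hexes, [None] * n, [(1.0, 1.2)], t)
    rejected = [i for i, r in enumerate(reasons) if r == "blink"]
    assert rejected == [9, 10, 11, 12, 13]


def test_single_frame_landmark_jump_is_instability():
    spec = SyntheticEyeSpec(noise_sigma=0.0)
    n, fps = 10, 10.0
    sets, hexes = _landmark_track(spec, n, fps)
    jumped = sets[5].points.copy()
    jumped[36:42] += (20.0, 0.0)  # right-eye hexagon jumps, face still
    sets[5] = type(sets[5])(points=jumped, frame_index=5, timestamp=0.5)
    hexes[5] = extract_eye_hexagons(sets[5])
    reasons = reject_frames(sets, hexes, [None] * n, [], np.arange(n) / fps)
    assert reasons[5] == "landmark_instability"


def test_whole_face_shift_is_motion():
    spec = SyntheticEyeSpec(noise_sigma=0.0)
    n, fps = 10, 10.0
    sets, hexes = _landmark_track(spec, n, fps)
    for i in range(5, n):  # head moves 12 px at frame 5 (> 0.1 EL = 6)
        moved = sets[i].points + (12.0, 0.0)
        sets[i] = type(sets[i])(points=moved, frame_index=i, timestamp=i / fps)
        hexes[i] = extract_eye_hexagons(sets[i])
    reasons = reject_frames(sets, hexes, [None] * n, [], np.arange(n) / fps)
    assert reasons[5] == "motion"
    assert reasons[6] == ""  # stationary again afterwards
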