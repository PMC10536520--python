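"""Per-frame exam metrics: lid distances, iris circle fit, alpha, grades."""

import numpy as np
import pytest

from oculid.landmarks import EyeHexagon
from oculid.metrics import (
    alpha_coordinate,
    alpha_pair_series,
    grade_ptosis_anatomic,
    grade_ptosis_time,
    iris_diameter,
    lateral_iris_point,
    ptosis_frame_metrics,
    IrisFit,
)
from oculid.segmentation import (
    HORIZONTAL,
    InterfaceCurve,
    SearchRectangle,
    SegmentationOutcome,
)


def flat_outcome(y, w=30, accepted=True):
    curve = InterfaceCurve(
        axis_values=np.arange(w, dtype=float) + 285.0,
        samples=np.full(w, float(y)),
        crossing_axis=HORIZONTAL,
        accepted=accepted,
    )
    rect = SearchRectangle((285, 0, 285 + w, 40), "lower_lid", HORIZONTAL,
                           (300.0, 20.0))
    return SegmentationOutcome(
        curve=curve if accepted else None,
        attempts=1, final_rectangle=rect,
        failure_reason="none" if accepted else "hypothesis",
    )


def eye_hex(x0=270.0, x1=330.0, cy=225.0):
    xa, xb = x0 + (x1 - x0) / 3, x0 + 2 * (x1 - x0) / 3
    return EyeHexagon(
        "right",
        np.array([[x0, cy], [xa, cy - 14], [xb, cy - 14],
                  [x1, cy], [xb, cy + 14], [xa, cy + 14]]),
    )


def test_frame_metrics_arithmetic_on_center_line():
    out = {
        "upper_lid": flat_outcome(10.0),
        "lower_lid": flat_outcome(20.0),
        "iris_bottom": flat_outcome(17.0),
    }
    m = ptosis_frame_metrics(out, eye_hex())
    assert m.valid
    assert m.lid_to_lid == pytest.approx(10.0)
    assert m.iris_to_lowerlid == pytest.approx(3.0)
    assert m.lid_to_lid_norm == pytest.approx(10.0 / 60.0)


def test_small_negative_iris_distance_tolerated():
    out = {
        "upper_lid": flat_outcome(10.0),
        "lower_lid": flat_outcome(20.0),
        "iris_bottom": flat_outcome(21.0),  # 1 px below the lower lid
    }
    m = ptosis_frame_metrics(out, eye_hex())
    assert m.valid
    assert m.iris_to_lowerlid == pytest.approx(-1.0)
    out["iris_bottom"] = flat_outcome(23.5)  # beyond the tolerance
    m2 = ptosis_frame_metrics(out, eye_hex())
    assert not m2.valid and m2.rejection_reason == "segmentation_failed"


def test_missing_required_curve_invalidates_frame():
    out = {"upper_lid": flat_outcome(10.0),
           "lower_lid": flat_outcome(20.0, accepted=False)}
    m = ptosis_frame_metrics(out, eye_hex())
    assert not m.valid and m.rejection_reason == "segmentation_failed"


def arc_curve(cx, cy, r, th0, th1, n=40, noise=0.0, seed=0):
    th = np.linspace(th0, th1, n)
    x = cx + r * np.cos(th)
    y = cy + r * np.sin(th)
    if noise:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0, noise, n)
    return InterfaceCurve(axis_values=x, samples=y, crossing_axis=HORIZONTAL)


def test_iris_diameter_exact_on_true_circle():
    fit = iris_diameter(arc_curve(0.0, 0.0, 12.0, 0.2, np.pi - 0.2))
    assert fit is not None
    assert fit.diameter == pytest.approx(24.0, abs=0.1)
    assert fit.reliable


def test_iris_diameter_degenerate_on_collinear_samples():
    line = InterfaceCurve(
        axis_values=np.arange(20, dtype=float),
        samples=np.full(20, 5.0),
        crossing_axis=HORIZONTAL,
    )
    assert iris_diameter(line) is None


def test_iris_diameter_robust_to_half_pixel_noise():
    fit = iris_diameter(arc_curve(0, 0, 15.0, 0.0, np.pi, noise=0.5, seed=3))
    assert fit is not None
    assert fit.diameter == pytest.approx(30.0, rel=0.02)


def test_short_arc_flagged_unreliable():
    fit = iris_diameter(arc_curve(0, 0, 12.0, 1.2, 1.6))  # ~23 degrees
    assert fit is not None and not fit.reliable


def test_alpha_endpoints_and_translation_invariance():
    hx = eye_hex()
    # P at the anchor corner (gaze left -> anchor is the max-x corner)
    a0, _ = alpha_coordinate((330.0, 225.0), hx, "left")
    assert a0 == pytest.approx(0.0, abs=1e-12)
    a1, _ = alpha_coordinate((270.0, 225.0), hx, "left")
    assert a1 == pytest.approx(1.0, abs=1e-12)
    # whole-image translation leaves the ratio unchanged
    shift = np.array([5.0, 3.0])
    hx2 = EyeHexagon("right", hx.vertices + shift)
    a2, _ = alpha_coordinate((290.0 + shift[0], 225.0 + shift[1]), hx2, "left")
    aref, _ = alpha_coordinate((290.0, 225.0), hx, "left")
    assert a2 == pytest.approx(aref, abs=1e-9)


def test_lateral_point_is_extremal_in_gaze_direction():
    ys = np.linspace(215, 235, 21)
    xs = 285.0 + np.sqrt(np.maximum(16.0**2 - (ys - 225.0) ** 2, 0.0))
    curve = InterfaceCurve(axis_values=ys, samples=xs, crossing_axis="vertical")
    P = lateral_iris_point(curve, "left")
    assert P[0] == pytest.approx(301.0)
    assert P[1] == pytest.approx(225.0)


def test_alpha_pair_constant_offset_is_not_drift():
    t = np.arange(0, 60.0, 0.5)
    pairs = alpha_pair_series(t, np.full_like(t, 0.5), np.full_like(t, 0.4))
    assert all(p.deviation == pytest.approx(0.0) for p in pairs)
    assert not any(p.misalignment_flag for p in pairs)
    assert pairs[0].baseline_delta == pytest.approx(0.1)


def test_alpha_pair_linear_drift_flags_after_threshold():
    t = np.arange(0, 60.0, 0.5)
    delta = t / 60.0 * 0.12  # drifts 0 -> 0.12
    pairs = alpha_pair_series(t, 0.5 + delta, np.full_like(t, 0.5))
    flags = np.array([p.misalignment_flag for p in pairs])
    assert flags.any() and not flags[0]
    first = t[np.argmax(flags)]
    # baseline ~ median of the first 5 s ~ 0.005; crossing of 0.05 + base
    assert 25.0 <= first <= 32.0
    later = flags[np.argmax(flags):]
    assert later.all()


def test_identical_alphas_never_flag():
    t = np.arange(0, 30.0, 0.5)
    a = 0.45 + 0.01 * np.sin(t)
    pairs = alpha_pair_series(t, a, a)
    assert all(p.deviation == pytest.approx(0.0) for p in pairs)


@pytest.mark.parametrize(
    "onset, expected",
    [(None, 0), (50.0, 0), (30.0, 1), (10.0, 2), (5.0, 2), (0.5, 3), (1.0, 3)],
)
def test_time_grade_scale(onset, expected):
    assert grade_ptosis_time(onset, series_duration=61.0) == expected


def test_time_grade_unavailable_for_short_series_without_onset():
    assert grade_ptosis_time(None, series_duration=30.0) is None


def test_time_grade_monotone_in_onset():
    onsets = [0.2, 0.9, 2.0, 9.0, 12.0, 44.0, 46.0, 60.0]
    grades = [grade_ptosis_time(o, 61.0) for o in onsets]
    assert all(a >= b for a, b in zip(grades, grades[1:]))


def test_anatomic_grade_bands():
    fit = IrisFit(center=(0.0, 100.0), diameter=24.0, arc_deg=120.0,
                  reliable=True)
    assert grade_ptosis_anatomic(80.0, fit) == 0  # above the iris top
    assert grade_ptosis_anatomic(90.0, fit) == 1  # above the pupil band
    assert grade_ptosis_anatomic(100.0, fit) == 2  # at the pupil center
    assert grade_ptosis_anatomic(112.0, fit) == 3  # half-diameter below
    assert grade_ptosis_anatomic(100.0, None) is None
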