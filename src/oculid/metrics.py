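"""Per-frame ptosis and diplopia metrics from accepted interface curves.

All vertical measurements are taken on the vertical line through the ROI
center and normalized by the eye length (EL), making them quasi-invariant
to small head translations and to image resolution.  Ocular alignment is
quantified by the barycentric coordinate α: the horizontal distance of
the visible lateral iris point to the anchoring eye corner, relative to
EL.  Severity grades follow the two 0-3 clinical scales (time-to-onset
and lid-versus-pupil position); the grade thresholds that the clinical
scales leave qualitative are configuration-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from oculid.config import DEFAULT_CONFIG, PipelineConfig
from oculid.landmarks import EyeHexagon
from oculid.segmentation import InterfaceCurve, SegmentationOutcome

REJECTION_REASONS = (
    "none",
    "no_landmarks",
    "bad_localization",
    "segmentation_failed",
    "blink",
    "motion",
    "lighting",
    "landmark_instability",
)


@dataclass
class FrameMeasurement:
    """All per-frame scalars for one eye, plus validity."""

    timestamp: float
    side: str
    upper_lid_y: float = float("nan")
    lower_lid_y: float = float("nan")
    iris_bottom_y: float = float("nan")
    lid_to_lid: float = float("nan")  # lower_lid_y - upper_lid_y
    iris_to_lowerlid: float = float("nan")  # lower_lid_y - iris_bottom_y
    lid_to_lid_norm: float = float("nan")
    iris_to_lowerlid_norm: float = float("nan")
    iris_diameter: float = float("nan")  # primary gaze only
    alpha: float = float("nan")  # diplopia frames only
    eye_length: float = float("nan")
    valid: bool = False
    rejection_reason: str = "none"


@dataclass
class AlphaPair:
    timestamp: float
    alpha_left: float
    alpha_right: float
    delta: float
    baseline_delta: float
    deviation: float
    misalignment_flag: bool


@dataclass
class IrisFit:
    center: tuple[float, float]
    diameter: float
    arc_deg: float
    reliable: bool


def ptosis_frame_metrics(
    outcomes: dict[str, SegmentationOutcome],
    hexagon: EyeHexagon,
    timestamp: float = 0.0,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> FrameMeasurement:
    """Evaluate accepted lid/iris curves on the ROI-center vertical line.

    Requires accepted upper- and lower-lid curves (iris bottom optional);
    a missing required curve invalidates the frame with reason
    ``segmentation_failed``.  A small negative iris-to-lower-lid distance
    (≥ -2 px, sub-pixel error) is tolerated.
    """
    m = FrameMeasurement(timestamp=timestamp, side=hexagon.side)
    el = abs(float(hexagon.vertices[3, 0] - hexagon.vertices[0, 0]))
    m.eye_length = el
    cx = float(hexagon.center[0])
    upper = outcomes.get("upper_lid")
    lower = outcomes.get("lower_lid")
    if not (upper and upper.accepted and lower and lower.accepted):
        m.valid = False
        m.rejection_reason = "segmentation_failed"
        return m
    m.upper_lid_y = upper.curve.value_at(cx)
    m.lower_lid_y = lower.curve.value_at(cx)
    m.lid_to_lid = m.lower_lid_y - m.upper_lid_y
    m.lid_to_lid_norm = m.lid_to_lid / el if el > 0 else float("nan")
    iris = outcomes.get("iris_bottom")
    if iris and iris.accepted:
        m.iris_bottom_y = iris.curve.value_at(cx)
        m.iris_to_lowerlid = m.lower_lid_y - m.iris_bottom_y
        m.iris_to_lowerlid_norm = (
            m.iris_to_lowerlid / el if el > 0 else float("nan")
        )
        if m.iris_to_lowerlid < -2.0:
            m.valid = False
            m.rejection_reason = "segmentation_failed"
            return m
    if m.lid_to_lid < 0:
        m.valid = False
        m.rejection_reason = "segmentation_failed"
        return m
    m.valid = True
    return m


def iris_diameter(
    arcs: list[InterfaceCurve] | InterfaceCurve,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> IrisFit | None:
    """Least-squares circle fit to iris-boundary arc samples.

    Uses the algebraic (Kåsa) fit.  Returns None for a degenerate fit
    (collinear samples); the fit is flagged unreliable when the arc
    subtends less than ``iris_min_arc_deg`` of the fitted circle.
    """
    if isinstance(arcs, InterfaceCurve):
        arcs = [arcs]
    xs, ys = [], []
    for arc in arcs:
        if arc.crossing_axis == "horizontal":
            xs.append(arc.axis_values)
            ys.append(arc.samples)
        else:
            xs.append(arc.samples)
            ys.append(arc.axis_values)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 3:
        return None
    # collinear samples admit no circle: check scatter around the best line
    centered = np.column_stack([x - x.mean(), y - y.mean()])
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 0.05:
        return None
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if not np.isfinite(r2) or r2 <= 0:
        return None
    r = float(np.sqrt(r2))
    span = max(x.max() - x.min(), y.max() - y.min())
    if r > 50.0 * max(span, 1.0):  # collinear-sample blow-up
        return None
    ang = np.unwrap(np.arctan2(y - cy, x - cx))
    arc_deg = float(np.degrees(ang.max() - ang.min()))
    return IrisFit(
        center=(float(cx), float(cy)),
        diameter=2.0 * r,
        arc_deg=arc_deg,
        reliable=arc_deg >= config.iris_min_arc_deg,
    )


def lateral_iris_point(curve: InterfaceCurve, gaze: str) -> tuple[float, float]:
    """Extremal point P of the lateral iris arc in the gaze direction.

    For gaze 'left' (iris displaced toward -x) the visible boundary is
    the rightmost arc point; for gaze 'right' the leftmost.
    """
    if gaze == "left":
        i = int(np.argmax(curve.samples))
    elif gaze == "right":
        i = int(np.argmin(curve.samples))
    else:
        raise ValueError("lateral gaze must be 'left' or 'right'")
    if curve.crossing_axis == "vertical":
        return float(curve.samples[i]), float(curve.axis_values[i])
    return float(curve.axis_values[i]), float(curve.samples[i])


def alpha_coordinate(
    P: tuple[float, float],
    hexagon: EyeHexagon,
    gaze: str,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[float, bool]:
    """Barycentric coordinate α = |x(P) − x(anchor corner)| / EL.

    The anchor is the eye corner from which the lateral search box was
    drawn — the corner opposite the gaze direction.  Returns (alpha,
    flagged) where flagged marks implausible values (> 1).  NaN for an
    under-resolved eye.
    """
    v = hexagon.vertices
    el = abs(float(v[3, 0] - v[0, 0]))
    if el < config.min_eye_length_px:
        return float("nan"), True
    if gaze == "left":
        anchor_x = float(v[:, 0].max())
    elif gaze == "right":
        anchor_x = float(v[:, 0].min())
    else:
        raise ValueError("lateral gaze must be 'left' or 'right'")
    alpha = abs(P[0] - anchor_x) / el
    return alpha, alpha > 1.0


def alpha_pair_series(
    timestamps: np.ndarray,
    alpha_left: np.ndarray,
    alpha_right: np.ndarray,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[AlphaPair]:
    """Per-frame α differences against their early-exercise baseline.

    delta = α_left − α_right; the baseline is the median delta over the
    first ``alpha_baseline_window_s`` seconds of frames where both eyes
    were measured; a constant offset therefore never flags.  Deviation
    beyond ``alpha_deviation_threshold`` raises the misalignment flag —
    reported, not diagnosed: interpretation stays with the physician.
    """
    t = np.asarray(timestamps, dtype=float)
    al = np.asarray(alpha_left, dtype=float)
    ar = np.asarray(alpha_right, dtype=float)
    ok = np.isfinite(al) & np.isfinite(ar)
    if not ok.any():
        return []
    delta = al - ar
    t0 = t[ok][0]
    base_mask = ok & (t <= t0 + config.alpha_baseline_window_s)
    baseline = float(np.median(delta[base_mask]))
    out = []
    for i in np.flatnonzero(ok):
        dev = abs(delta[i] - baseline)
        out.append(
            AlphaPair(
                timestamp=float(t[i]),
                alpha_left=float(al[i]),
                alpha_right=float(ar[i]),
                delta=float(delta[i]),
                baseline_delta=baseline,
                deviation=float(dev),
                misalignment_flag=dev > config.alpha_deviation_threshold,
            )
        )
    return out


def droop_onset_time(
    timestamps: np.ndarray,
    filtered: np.ndarray,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> float | None:
    """First time the filtered lid opening drops below the onset fraction
    of its initial value; None if it never does."""
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(filtered, dtype=float)
    ok = np.isfinite(v)
    if not ok.any():
        return None
    t, v = t[ok], v[ok]
    v0 = v[0]
    if v0 <= 0:
        return None
    below = v < config.droop_onset_frac * v0
    if not below.any():
        return None
    return float(t[np.argmax(below)] - t[0])


def grade_ptosis_time(
    onset: float | None, series_duration: float = 61.0
) -> int | None:
    """Time-to-onset severity: 0 none within 45 s, 1 within 11-45 s,
    2 within 10 s, 3 immediate.  A short series without onset cannot
    certify grade 0 and returns None."""
    if onset is None:
        return 0 if series_duration >= 45.0 else None
    if onset > 45.0:
        return 0
    if onset > 10.0:
        return 1
    if onset > 1.0:
        return 2
    return 3


def grade_ptosis_anatomic(
    upper_lid_y: float,
    iris_fit: IrisFit | None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> int | None:
    """Lid-versus-pupil severity, pupil approximated by the iris center.

    0: lid above the iris top; 1: between iris top and a quarter-diameter
    above the pupil center; 2: within a quarter-diameter of the center
    ("at pupil"); 3: below that band.  None without a usable iris fit.
    """
    if iris_fit is None or not np.isfinite(upper_lid_y):
        return None
    cy = iris_fit.center[1]
    r = iris_fit.diameter / 2.0
    band = config.pupil_band_frac * iris_fit.diameter
    iris_top = cy - r
    if upper_lid_y < iris_top:
        return 0
    if upper_lid_y < cy - band:
        return 1
    if upper_lid_y <= cy + band:
        return 2
    return 3
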