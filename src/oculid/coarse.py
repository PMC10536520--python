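"""First-approximation ptosis metrics from the eye hexagons alone.

Eyelid distance (ED), eye area and eye length (EL) come straight from the
six eye-contour landmarks; ED and area are normalized by EL (and EL²) so
they are quasi-invariant to small head motion and to image resolution.
Blinks appear as sharp downward ED spikes and are detected against a
rolling baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from oculid.config import DEFAULT_CONFIG, PipelineConfig
from oculid.landmarks import EyeHexagon


@dataclass
class CoarseEyeMetrics:
    side: str
    eyelid_distance: float  # px
    eye_area: float  # px^2
    eye_length: float  # px
    ed_normalized: float  # ED / EL
    area_normalized: float  # area / EL^2
    available: bool = True
    under_resolved: bool = False


def eyelid_distance(hexagon: EyeHexagon) -> float:
    """Mean vertical distance between the paired upper/lower lid landmarks.

    Right eye pairs 38<->41 and 39<->42; left eye pairs 44<->48 and
    45<->47 (1-based annotation indices).  Defined for a degenerate
    (closed-eye) hexagon too — a blink reads as ED ≈ 0.
    """
    y = hexagon.vertices[:, 1]
    if hexagon.side == "right":
        pairs = ((1, 4), (2, 5))
    else:
        pairs = ((1, 5), (2, 4))
    return float(np.mean([abs(y[b] - y[a]) for a, b in pairs]))


def eye_length(
    hexagon: EyeHexagon, config: PipelineConfig = DEFAULT_CONFIG
) -> tuple[float, bool]:
    """Horizontal corner-to-corner distance and an under-resolved flag."""
    el = abs(float(hexagon.vertices[3, 0] - hexagon.vertices[0, 0]))
    return el, el < config.min_eye_length_px


def eye_area(hexagon: EyeHexagon) -> float:
    """Shoelace area of the six-vertex eye outline, orientation-free.

    NaN when the outline self-intersects (no meaningful enclosed area).
    """
    if hexagon.degenerate:
        v = hexagon.vertices
        x, y = v[:, 0], v[:, 1]
        return float(
            abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0
        )
    poly = Polygon(hexagon.vertices)
    if not poly.is_valid:
        return float("nan")
    return float(poly.area)


def coarse_eye_metrics(
    hexagon: EyeHexagon, config: PipelineConfig = DEFAULT_CONFIG
) -> CoarseEyeMetrics:
    ed = eyelid_distance(hexagon)
    el, under = eye_length(hexagon, config)
    area = eye_area(hexagon)
    return CoarseEyeMetrics(
        side=hexagon.side,
        eyelid_distance=ed,
        eye_area=area,
        eye_length=el,
        ed_normalized=ed / el if el > 0 else float("nan"),
        area_normalized=area / el**2 if el > 0 else float("nan"),
        under_resolved=under,
    )


def detect_blinks(
    ed_series: np.ndarray,
    timestamps: np.ndarray,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[list[tuple[float, float]], float]:
    """Blink events and blink rate per minute from a per-frame ED series.

    A blink is a maximal run of frames where ED drops below
    ``blink_rel_threshold`` times a rolling-median baseline (window
    ``blink_baseline_window_s``), lasting at most ``blink_max_duration_s``;
    single-frame spikes count.  NaN frames break runs and are ignored by
    the baseline.
    """
    ed = np.asarray(ed_series, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    ok = np.isfinite(ed)
    if not ok.any() or len(ed) < 2:
        return [], 0.0
    half = config.blink_baseline_window_s / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    baseline = np.full_like(ed, np.nan)
    for i in range(len(ed)):
        window = ed[lo[i] : hi[i]]
        window = window[np.isfinite(window)]
        if window.size:
            baseline[i] = np.median(window)
    below = ok & np.isfinite(baseline) & (ed < config.blink_rel_threshold * baseline)
    events: list[tuple[float, float]] = []
    i = 0
    n = len(ed)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            if t[j] - t[i] <= config.blink_max_duration_s:
                events.append((float(t[i]), float(t[j])))
            i = j + 1
        else:
            i += 1
    span = float(t[-1] - t[0])
    rate = len(events) / span * 60.0 if span > 0 else 0.0
    return events, rate
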