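"""Exercise windows, frame rejection, gap-aware series, filtering, trends.

The per-frame metrics form a time series that is not continuous in time:
frames failing the stability, lighting, landmark-instability or blink
checks are dropped.  Holes up to one second are filled by linear
interpolation on the native frame grid; longer gaps are recorded and
never bridged — not by interpolation and not by the filter.  Smoothing
uses a spectral low-pass suited to non-periodic signals: each contiguous
segment is mirror-extended to twice its length (removing the periodicity
mismatch at the boundaries), sharply low-passed in the Fourier domain and
truncated back, which preserves constants and linear ramps while strongly
attenuating high-frequency noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import draw as skdraw

from oculid.config import DEFAULT_CONFIG, PipelineConfig
from oculid.landmarks import EyeHexagon, LandmarkSet
from oculid.segmentation import SegmentationOutcome, segment_two_cluster

CHANNELS = (
    "lid_to_lid_norm",
    "iris_to_lowerlid_norm",
    "alpha_left",
    "alpha_right",
    "alpha_delta",
    "ed_norm",
    "area_norm",
)


@dataclass
class MeasurementSeries:
    """Time-stamped channel with gap records and processed variants."""

    channel: str
    timestamps: np.ndarray  # valid sample times, strictly increasing
    values: np.ndarray
    grid_timestamps: np.ndarray  # native acquisition grid
    interpolated: np.ndarray  # on the grid; NaN inside >1 s gaps
    gaps: list[tuple[float, float]] = field(default_factory=list)
    filtered: np.ndarray | None = None
    trend: tuple[float, float] | None = None  # (intercept, slope)
    flags: list = field(default_factory=list)


@dataclass
class ExerciseWindow:
    exercise: str  # {ptosis_up, diplopia_left, diplopia_right}
    start: float
    end: float
    atypical: bool = False  # duration outside the nominal [40, 80] s


# ---------------------------------------------------------------------------
# gaze classification and exercise-window detection
# ---------------------------------------------------------------------------


def classify_gaze(
    image: np.ndarray,
    hexagon: EyeHexagon,
    seed: int = 0,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> str:
    """Gaze label from the scleral layout inside the eye hexagon.

    Two-cluster the hexagon interior into iris-like (dark) and
    sclera-like (bright) pixels; the position of the sclera centroid
    relative to the iris centroid encodes gaze: sclera below → up-gaze,
    sclera right of the iris → gaze left, etc.  Returns one of
    {up, left, right, primary, unknown}.
    """
    if hexagon.degenerate:
        return "unknown"
    v = hexagon.vertices
    el = abs(float(v[3, 0] - v[0, 0]))
    rr, cc = skdraw.polygon(v[:, 1], v[:, 0], shape=image.shape)
    if len(rr) < 16:
        return "unknown"
    vals = image[rr, cc]
    if vals.max() - vals.min() <= 1e-9:
        return "unknown"
    try:
        lab, _ = segment_two_cluster(vals.reshape(-1, 1), seed, config)
    except ValueError:
        return "unknown"
    lab = lab.ravel()
    if not lab.any() or lab.all():
        return "unknown"
    bright_cx, bright_cy = cc[lab == 1].mean(), rr[lab == 1].mean()
    dark_cx, dark_cy = cc[lab == 0].mean(), rr[lab == 0].mean()
    dx = bright_cx - dark_cx
    dy = bright_cy - dark_cy
    thresh = 0.06 * el
    if abs(dy) >= abs(dx):
        if dy > thresh:
            return "up"
        return "primary"
    if dx > thresh:
        return "left"  # sclera right of the iris: iris displaced left
    if dx < -thresh:
        return "right"
    return "primary"


_EXPECTED = {"ptosis_up": "up", "diplopia_left": "left", "diplopia_right": "right"}


def detect_exercise_window(
    labels_right: list[str],
    labels_left: list[str],
    timestamps: np.ndarray,
    exercise: str,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> ExerciseWindow | None:
    """Longest run of the expected gaze label, eyes required to agree.

    Frames where the two eyes disagree are excluded (vote 0); the
    per-frame vote (+1 expected, −1 other) is smoothed by a majority vote
    over ``gaze_vote_window_s``.  Neutral stretches up to
    ``window_bridge_s`` (blinks, rest closures) do not split a run; runs
    shorter than ``min_exercise_run_s`` give no window.
    """
    expected = _EXPECTED[exercise]
    t = np.asarray(timestamps, dtype=float)
    n = len(t)
    vote = np.zeros(n)
    for i, (r, l) in enumerate(zip(labels_right, labels_left)):
        if r != l or r == "unknown":
            continue  # eyes must be consistent
        vote[i] = 1.0 if r == expected else -1.0
    half = config.gaze_vote_window_s / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    smooth = np.array([
        vote[lo[i]:hi[i]].sum() for i in range(n)
    ])
    inwin = smooth > 0
    # bridge short neutral stretches (no counter-votes) inside a run
    for i0, i1 in _segments(~inwin):
        if i0 == 0 or i1 == n:
            continue
        if (
            t[i1 - 1] - t[i0] <= config.window_bridge_s
            and not (vote[i0:i1] < 0).any()
        ):
            inwin[i0:i1] = True
    best = None
    i = 0
    while i < n:
        if inwin[i]:
            j = i
            while j + 1 < n and inwin[j + 1]:
                j += 1
            if best is None or t[j] - t[i] > best[1] - best[0]:
                best = (t[i], t[j])
            i = j + 1
        else:
            i += 1
    if best is None or best[1] - best[0] < config.min_exercise_run_s:
        return None
    dur = best[1] - best[0]
    return ExerciseWindow(
        exercise=exercise,
        start=float(best[0]),
        end=float(best[1]),
        atypical=not (config.exercise_min_s <= dur <= config.exercise_max_s),
    )


# ---------------------------------------------------------------------------
# frame rejection
# ---------------------------------------------------------------------------


def reject_frames(
    landmark_sets: list[LandmarkSet | None],
    hexagons: list[tuple[EyeHexagon, EyeHexagon] | None],
    outcomes: list[dict[str, SegmentationOutcome] | None],
    blink_events: list[tuple[float, float]],
    timestamps: np.ndarray,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[str]:
    """Per-frame rejection reason ('' = kept), exclusive by priority.

    motion: median landmark displacement between consecutive frames
    exceeds ``motion_max_disp_frac``·EL.  lighting: any search rectangle
    failed the connectedness hypothesis H4 (non-connex clusters, e.g.
    reflections).  landmark_instability: the eye-hexagon centroid jumps
    while the face as a whole stays still.  blink: the frame falls inside
    a detected blink event ± one frame period.
    """
    t = np.asarray(timestamps, dtype=float)
    n = len(t)
    dt = float(np.median(np.diff(t))) if n > 1 else 0.0
    reasons = [""] * n
    for i in range(n):
        lm = landmark_sets[i]
        if lm is None or hexagons[i] is None:
            continue  # handled upstream as no_landmarks
        right, left = hexagons[i]
        el = abs(float(right.vertices[3, 0] - right.vertices[0, 0]))
        prev = landmark_sets[i - 1] if i > 0 else None
        if prev is not None and el > 0:
            disp = np.linalg.norm(lm.points - prev.points, axis=1)
            face_move = float(np.median(disp))
            if face_move > config.motion_max_disp_frac * el:
                reasons[i] = "motion"
                continue
            eye_jump = 0.0
            if hexagons[i - 1] is not None:
                pr, pl = hexagons[i - 1]
                eye_jump = max(
                    float(np.linalg.norm(right.center - pr.center)),
                    float(np.linalg.norm(left.center - pl.center)),
                )
        else:
            face_move, eye_jump = 0.0, 0.0
        out = outcomes[i]
        h4_failed = False
        if out:
            for o in out.values():
                if o.last_quality is not None and o.last_quality.get("H4") is False:
                    h4_failed = True
                    break
        if h4_failed:
            reasons[i] = "lighting"
            continue
        if (
            prev is not None
            and el > 0
            and eye_jump > config.instability_jump_frac * el
            and face_move < config.instability_face_still_frac * el
        ):
            reasons[i] = "landmark_instability"
            continue
        for start, end in blink_events:
            if start - dt <= t[i] <= end + dt:
                reasons[i] = "blink"
                break
    return reasons


# ---------------------------------------------------------------------------
# series assembly, filtering, trend
# ---------------------------------------------------------------------------


def assemble_series(
    timestamps: np.ndarray,
    values: np.ndarray,
    grid_timestamps: np.ndarray | None = None,
    channel: str = "lid_to_lid_norm",
    config: PipelineConfig = DEFAULT_CONFIG,
) -> MeasurementSeries:
    """Sorted valid samples, ≤1 s holes interpolated, longer gaps recorded.

    ``grid_timestamps`` is the native acquisition grid (defaults to the
    valid-sample times); interpolation is linear between bracketing valid
    samples, never inside a recorded gap and never outside the sampled
    support.
    """
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(v)
    t, v = t[ok], v[ok]
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    if grid_timestamps is None:
        grid = t.copy()
    else:
        grid = np.asarray(grid_timestamps, dtype=float)
    if len(t) < 2:
        return MeasurementSeries(
            channel=channel,
            timestamps=t,
            values=v,
            grid_timestamps=grid,
            interpolated=np.full(len(grid), np.nan),
            flags=["too_few_samples"],
        )
    gaps = [
        (float(t[i]), float(t[i + 1]))
        for i in range(len(t) - 1)
        if t[i + 1] - t[i] > config.max_interp_gap_s
    ]
    interp = np.interp(grid, t, v, left=np.nan, right=np.nan)
    for start, end in gaps:
        hole = (grid > start) & (grid < end)
        interp[hole] = np.nan
    outside = (grid < t[0]) | (grid > t[-1])
    interp[outside] = np.nan
    return MeasurementSeries(
        channel=channel,
        timestamps=t,
        values=v,
        grid_timestamps=grid,
        interpolated=interp,
        gaps=gaps,
    )


def _segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index ranges."""
    out = []
    i, n = 0, len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return out


def filter_series(
    series: MeasurementSeries, config: PipelineConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Mirrored sharp spectral low-pass per contiguous segment.

    Each contiguous interpolated segment is resampled uniformly at its
    mean frame rate, extended by its mirror image (even extension, so the
    periodic transform sees no boundary jump), transformed, components
    above ``filter_cutoff_hz`` zeroed, inverted and truncated to the
    original support, then mapped back to the native grid.  Segments
    shorter than ``filter_min_segment_s`` pass through unfiltered
    (flagged).  Gaps are left as NaN — never bridged.
    """
    grid = series.grid_timestamps
    x = series.interpolated
    out = np.full_like(x, np.nan)
    for i0, i1 in _segments(np.isfinite(x)):
        seg_t = grid[i0:i1]
        seg_v = x[i0:i1]
        span = seg_t[-1] - seg_t[0]
        if span < config.filter_min_segment_s or len(seg_v) < 4:
            out[i0:i1] = seg_v
            if "unfiltered_segment" not in series.flags:
                series.flags.append("unfiltered_segment")
            continue
        n = len(seg_v)
        ut = np.linspace(seg_t[0], seg_t[-1], n)
        uv = np.interp(ut, seg_t, seg_v)
        ext = np.concatenate([uv, uv[::-1]])
        dt = (ut[-1] - ut[0]) / (n - 1)
        spec = np.fft.rfft(ext)
        freqs = np.fft.rfftfreq(2 * n, d=dt)
        spec[freqs > config.filter_cutoff_hz] = 0.0
        smoothed = np.fft.irfft(spec, n=2 * n)[:n]
        out[i0:i1] = np.interp(seg_t, ut, smoothed)
    series.filtered = out
    return out


def fit_trend(
    series: MeasurementSeries,
    use_filtered: bool = True,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[float, float] | None:
    """Ordinary least squares on normalized time over the non-gap support.

    Time is normalized to [0, 1] across the series grid, so the slope is
    the channel's total change over the exercise window.  Requires ≥ 10
    samples spanning at least half of the window; returns (intercept,
    slope) or None.
    """
    grid = series.grid_timestamps
    v = series.filtered if (use_filtered and series.filtered is not None) else (
        series.interpolated
    )
    ok = np.isfinite(v)
    if ok.sum() < 10 or len(grid) < 2:
        return None
    span = grid[-1] - grid[0]
    if span <= 0 or (grid[ok][-1] - grid[ok][0]) < 0.5 * span:
        return None
    tn = (grid - grid[0]) / span
    slope, intercept = np.polyfit(tn[ok], v[ok], 1)
    series.trend = (float(intercept), float(slope))
    return series.trend
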