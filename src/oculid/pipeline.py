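"""End-to-end composition: frames in, metrics, series, grades and files out.

Order of operations per clip: landmarks → localization validity → coarse
metrics and gaze label → local interface segmentation → per-frame exam
metrics; then blink detection, frame rejection, exercise-window
detection, channel assembly with gap records, spectral filtering, trend
fits, droop onset and grades.  Every frame is accounted for exactly once
in the summary's disposition counts, and the whole run is deterministic
given the clip, the configuration and the base seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from oculid.coarse import coarse_eye_metrics, detect_blinks
from oculid.config import DEFAULT_CONFIG, PipelineConfig
from oculid.io import ClipDescriptor, read_frames, write_overlay
from oculid.landmarks import (
    EyeHexagon,
    FixtureLandmarkProvider,
    LandmarkSet,
    extract_eye_hexagons,
    face_box_from_landmarks,
    read_landmarks_csv,
    validate_eye_localization,
)
from oculid.metrics import (
    FrameMeasurement,
    alpha_coordinate,
    alpha_pair_series,
    droop_onset_time,
    grade_ptosis_anatomic,
    grade_ptosis_time,
    iris_diameter,
    lateral_iris_point,
    ptosis_frame_metrics,
)
from oculid.segmentation import segment_eye
from oculid.synthetic import SyntheticEyeSpec, render_frame, sequence_jitters
from oculid.timeseries import (
    MeasurementSeries,
    assemble_series,
    classify_gaze,
    detect_exercise_window,
    filter_series,
    fit_trend,
    reject_frames,
)

SIDES = ("right", "left")
SIDE_CHANNELS = ("lid_to_lid_norm", "iris_to_lowerlid_norm", "ed_norm", "area_norm")


@dataclass
class PipelineResult:
    summary: dict
    frames: pd.DataFrame
    series: dict[str, MeasurementSeries]
    window: object | None
    config: PipelineConfig

    @property
    def complete(self) -> bool:
        """True when no headline metric came back unavailable."""
        return not self.summary.get("unavailable_metrics")


def _frame_stream(source, sample_every_s, config):
    """Yield (index, t, image) plus a default landmark provider."""
    if isinstance(source, SyntheticEyeSpec):
        spec = source
        step = 1
        if sample_every_s:
            step = max(1, int(round(sample_every_s * spec.fps)))
        jitters = sequence_jitters(spec)
        provider = FixtureLandmarkProvider(spec, jitters=jitters)

        def gen():
            for i in range(0, spec.n_frames, step):
                frame, _ = render_frame(spec, i / spec.fps, tuple(jitters[i]))
                yield i, i / spec.fps, frame

        return gen(), provider
    clip = source
    if sample_every_s is not None and clip.sample_every_s is None:
        clip = ClipDescriptor(
            source=clip.source,
            fps=clip.fps,
            exercise_hint=clip.exercise_hint,
            frame_range=clip.frame_range,
            sample_every_s=sample_every_s,
            sample_every_n=clip.sample_every_n,
        )
    return read_frames(clip), None


def run_pipeline(
    source: ClipDescriptor | SyntheticEyeSpec,
    exercise: str = "ptosis",
    gaze: str | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
    provider=None,
    landmarks_csv: str | Path | None = None,
    out_dir: str | Path | None = None,
    sample_every_s: float | None = None,
    write_overlays: bool = False,
) -> PipelineResult:
    """Run the full ptosis/diplopia pipeline on one clip.

    ``source`` is a clip descriptor (video file or frame directory) or a
    synthetic spec rendered in memory.  ``provider`` supplies landmarks
    per frame; for a synthetic source it defaults to the ground-truth
    fixture provider, for a clip either a provider or a precomputed
    landmark CSV is required.  Writes per-frame CSV, per-channel series
    CSVs and a summary JSON under ``out_dir`` when given.
    """
    if exercise == "ptosis":
        gaze = gaze or "up"
        window_key = "ptosis_up"
    elif exercise == "diplopia":
        if gaze not in ("left", "right"):
            raise ValueError("diplopia requires gaze 'left' or 'right'")
        window_key = f"diplopia_{gaze}"
    else:
        raise ValueError(f"unknown exercise {exercise!r}")

    stream, default_provider = _frame_stream(source, sample_every_s, config)
    provider = provider or default_provider
    lookup: dict[int, LandmarkSet] | None = None
    if landmarks_csv is not None:
        lookup = {s.frame_index: s for s in read_landmarks_csv(landmarks_csv)}
    if provider is None and lookup is None:
        raise ValueError("a landmark provider or landmark CSV is required")

    idxs: list[int] = []
    times: list[float] = []
    lm_sets: list[LandmarkSet | None] = []
    hexes: list[tuple[EyeHexagon, EyeHexagon] | None] = []
    gaze_labels = {"right": [], "left": []}
    outcomes: list[dict | None] = []
    measures: list[dict[str, FrameMeasurement | None]] = []
    coarse_rows: list[dict] = []
    iris_fits: list = []
    loc_invalid: list[bool] = []
    image_shape = None
    overlay_dir = Path(out_dir) / "overlays" if (out_dir and write_overlays) else None
    if overlay_dir:
        overlay_dir.mkdir(parents=True, exist_ok=True)
    last_overlay_t = -1e9

    for i, t, image in stream:
        image_shape = image.shape
        idxs.append(i)
        times.append(t)
        if lookup is not None:
            lm = lookup.get(i)
        else:
            lm = provider(image, frame_index=i, timestamp=t)
        if lm is not None and not lm.in_bounds(image.shape):
            lm = None
        lm_sets.append(lm)
        if lm is None:
            hexes.append(None)
            loc_invalid.append(False)
            outcomes.append(None)
            measures.append({"right": None, "left": None})
            coarse_rows.append({})
            iris_fits.append(None)
            for side in SIDES:
                gaze_labels[side].append("unknown")
            continue
        right, left = extract_eye_hexagons(lm)
        hexes.append((right, left))
        ok, _reason = validate_eye_localization(
            right, left, face_box_from_landmarks(lm, config.face_box_inflate),
            config,
        )
        loc_invalid.append(not ok)
        # coarse metrics stay defined even for a degenerate (closed) eye:
        # a blink must read as ED ~ 0, not as a missing sample
        crow = {
            "right": coarse_eye_metrics(right, config),
            "left": coarse_eye_metrics(left, config),
        }
        if not ok:
            outcomes.append(None)
            measures.append({"right": None, "left": None})
            coarse_rows.append(crow)
            iris_fits.append(None)
            for side in SIDES:
                gaze_labels[side].append("unknown")
            continue
        per_eye_outcomes = {}
        per_eye_measures = {}
        fit = None
        for side, hexagon in (("right", right), ("left", left)):
            if hexagon.degenerate:
                gaze_labels[side].append("unknown")
                per_eye_outcomes[side] = {}
                m = FrameMeasurement(timestamp=t, side=side)
                m.rejection_reason = "segmentation_failed"
                per_eye_measures[side] = m
                continue
            gaze_labels[side].append(
                classify_gaze(image, hexagon, seed=config.base_seed, config=config)
            )
            seg = segment_eye(
                image,
                hexagon,
                exercise,
                gaze=gaze,
                base_seed=config.base_seed + 17 * i + (0 if side == "right" else 501),
                config=config,
            )
            per_eye_outcomes[side] = seg
            m = ptosis_frame_metrics(seg, hexagon, timestamp=t, config=config)
            if exercise == "diplopia":
                # the required diplopia metric is the lateral iris point;
                # lid curves are a bonus (they fail more often in lateral
                # gaze, where the iris abuts the lid interfaces)
                lat = seg.get("iris_lateral")
                if lat and lat.accepted:
                    P = lateral_iris_point(lat.curve, gaze)
                    m.alpha, _flagged = alpha_coordinate(P, hexagon, gaze, config)
                    m.valid = True
                    m.rejection_reason = "none"
                else:
                    m.valid = False
                    m.rejection_reason = "segmentation_failed"
            else:
                ib = seg.get("iris_bottom")
                if ib and ib.accepted and side == "right" and fit is None:
                    fit = iris_diameter(ib.curve, config)
            per_eye_measures[side] = m
        required = (
            ("iris_lateral",) if exercise == "diplopia"
            else ("upper_lid", "lower_lid", "iris_bottom")
        )
        outcomes.append(
            {f"{s}_{k}": v for s, seg in per_eye_outcomes.items()
             for k, v in seg.items() if k in required}
        )
        measures.append(per_eye_measures)
        coarse_rows.append(crow)
        iris_fits.append(fit)
        if overlay_dir and t - last_overlay_t >= 2.0:
            rects, curves = [], []
            for seg in per_eye_outcomes.values():
                for o in seg.values():
                    rects.append(o.final_rectangle)
                    curves.append(o.curve)
            write_overlay(image, rects, curves, lm.points,
                          overlay_dir / f"overlay_{i:05d}.png")
            last_overlay_t = t

    t_arr = np.asarray(times, dtype=float)
    n = len(t_arr)
    if n == 0:
        raise OSError("clip yielded no frames")

    # --- blinks from the coarse ED series, per eye ---------------------
    blink = {}
    for side in SIDES:
        ed = np.array(
            [
                (coarse_rows[i].get(side).eyelid_distance
                 if coarse_rows[i].get(side) else np.nan)
                for i in range(n)
            ]
        )
        events, rate = detect_blinks(ed, t_arr, config)
        blink[side] = {"events": events, "rate_per_min": rate}
    union_events = sorted(set(blink["right"]["events"]) | set(blink["left"]["events"]))
    synchronized = all(
        any(re[0] <= le[1] and le[0] <= re[1] for le in blink["left"]["events"])
        for re in blink["right"]["events"]
    ) if blink["right"]["events"] else True

    # --- rejection and disposition -------------------------------------
    reasons = reject_frames(lm_sets, hexes, outcomes, union_events, t_arr, config)
    disposition = []
    for i in range(n):
        if lm_sets[i] is None:
            disposition.append("no_landmarks")
        elif loc_invalid[i]:
            disposition.append("bad_localization")
        elif reasons[i]:
            disposition.append(reasons[i])
        else:
            ms = measures[i]
            ok_sides = [s for s in SIDES if ms[s] is not None and ms[s].valid]
            disposition.append("used" if ok_sides else "segmentation_failed")
    disposition = np.array(disposition)

    # --- exercise window ------------------------------------------------
    window = detect_exercise_window(
        gaze_labels["right"], gaze_labels["left"], t_arr, window_key, config
    )
    if window is not None:
        in_window = (t_arr >= window.start) & (t_arr <= window.end)
    else:
        in_window = np.ones(n, dtype=bool)
    grid = t_arr[in_window]

    # --- channel series -------------------------------------------------
    series: dict[str, MeasurementSeries] = {}

    def add_series(name, sample_t, sample_v):
        s = assemble_series(sample_t, sample_v, grid_timestamps=grid,
                            channel=name, config=config)
        filter_series(s, config)
        fit_trend(s, config=config)
        series[name] = s

    for side in SIDES:
        usable = [
            i for i in range(n)
            if in_window[i] and disposition[i] == "used"
            and measures[i][side] is not None and measures[i][side].valid
        ]
        st = t_arr[usable]
        add_series(f"{side}_lid_to_lid_norm", st,
                   [measures[i][side].lid_to_lid_norm for i in usable])
        add_series(f"{side}_iris_to_lowerlid_norm", st,
                   [measures[i][side].iris_to_lowerlid_norm for i in usable])
        cidx = [
            i for i in range(n)
            if in_window[i] and disposition[i] in ("used", "segmentation_failed")
            and coarse_rows[i].get(side) and coarse_rows[i][side].available
        ]
        add_series(f"{side}_ed_norm", t_arr[cidx],
                   [coarse_rows[i][side].ed_normalized for i in cidx])
        add_series(f"{side}_area_norm", t_arr[cidx],
                   [coarse_rows[i][side].area_normalized for i in cidx])

    alpha_summary = None
    if exercise == "diplopia":
        al = np.array([
            measures[i]["left"].alpha if measures[i]["left"] is not None else np.nan
            for i in range(n)
        ])
        ar = np.array([
            measures[i]["right"].alpha if measures[i]["right"] is not None else np.nan
            for i in range(n)
        ])
        keep = in_window & (disposition == "used")
        al = np.where(keep, al, np.nan)
        ar = np.where(keep, ar, np.nan)
        pairs = alpha_pair_series(t_arr, al, ar, config)
        ok = np.isfinite(al) & np.isfinite(ar)
        add_series("alpha_left", t_arr[ok], al[ok])
        add_series("alpha_right", t_arr[ok], ar[ok])
        add_series("alpha_delta", t_arr[ok], (al - ar)[ok])
        if pairs:
            alpha_summary = {
                "baseline_delta": pairs[0].baseline_delta,
                "max_deviation": max(p.deviation for p in pairs),
                "misalignment_flagged": any(p.misalignment_flag for p in pairs),
            }

    # --- onset, decay, grades ------------------------------------------
    unavailable = []
    decay = {}
    onsets = {}
    for side in SIDES:
        s = series[f"{side}_lid_to_lid_norm"]
        if s.trend is not None and s.trend[0] > 0:
            decay[side] = -s.trend[1] / s.trend[0]
        else:
            decay[side] = None
            unavailable.append(f"{side}_lid_trend")
        if s.filtered is not None and len(s.grid_timestamps):
            onsets[side] = droop_onset_time(s.grid_timestamps, s.filtered, config)
        else:
            onsets[side] = None
    span = float(grid[-1] - grid[0]) if len(grid) > 1 else 0.0
    onset_vals = [o for o in onsets.values() if o is not None]
    onset = min(onset_vals) if onset_vals else None
    grade_time = grade_ptosis_time(onset, series_duration=span)
    fit = next((f for f in iris_fits if f is not None and f.reliable), None)
    upper_frames = [
        measures[i]["right"] for i in range(n)
        if measures[i]["right"] is not None and measures[i]["right"].valid
    ]
    grade_anat = None
    if fit is not None and upper_frames:
        grade_anat = grade_ptosis_anatomic(upper_frames[-1].upper_lid_y, fit, config)
    if exercise == "ptosis" and grade_time is None:
        unavailable.append("grade_time")
    if window is None:
        unavailable.append("exercise_window")

    counts = {
        key: int((disposition == key).sum())
        for key in (
            "used", "segmentation_failed", "blink", "motion", "lighting",
            "landmark_instability", "bad_localization", "no_landmarks",
        )
    }
    assert sum(counts.values()) == n  # every frame accounted exactly once

    lid_gaps = series["right_lid_to_lid_norm"].gaps
    summary = {
        "exercise": exercise,
        "gaze": gaze,
        "n_frames": n,
        "disposition": counts,
        "fraction_used": counts["used"] / n,
        "window": (
            {"start": window.start, "end": window.end, "atypical": window.atypical}
            if window is not None else None
        ),
        "blink": {
            side: {
                "n_events": len(blink[side]["events"]),
                "rate_per_min": blink[side]["rate_per_min"],
                "events": [list(e) for e in blink[side]["events"]],
            }
            for side in SIDES
        },
        "blink_synchronized": bool(synchronized),
        "gaps": [list(g) for g in lid_gaps],
        "trends": {
            name: (
                {"intercept": s.trend[0], "slope": s.trend[1]}
                if s.trend is not None else None
            )
            for name, s in series.items()
        },
        "lid_decay_fraction": decay,
        "droop_onset_s": onset,
        "grade_time": grade_time,
        "grade_anatomic": grade_anat,
        "alpha": alpha_summary,
        "unavailable_metrics": unavailable,
        "base_seed": config.base_seed,
    }

    frames_df = _frames_table(idxs, t_arr, disposition, gaze_labels,
                              coarse_rows, measures)
    if out_dir is not None:
        _write_outputs(Path(out_dir), summary, frames_df, series)
    return PipelineResult(
        summary=summary, frames=frames_df, series=series,
        window=window, config=config,
    )


def _frames_table(idxs, t_arr, disposition, gaze_labels, coarse_rows, measures):
    rows = []
    for i in range(len(idxs)):
        row = {
            "frame_index": idxs[i],
            "t": t_arr[i],
            "disposition": disposition[i],
            "gaze_right": gaze_labels["right"][i],
            "gaze_left": gaze_labels["left"][i],
        }
        for side in SIDES:
            cm = coarse_rows[i].get(side)
            row[f"{side}_ed"] = cm.eyelid_distance if cm else np.nan
            row[f"{side}_el"] = cm.eye_length if cm else np.nan
            row[f"{side}_area"] = cm.eye_area if cm else np.nan
            m = measures[i][side]
            for name in (
                "upper_lid_y", "lower_lid_y", "iris_bottom_y", "lid_to_lid",
                "lid_to_lid_norm", "iris_to_lowerlid", "iris_to_lowerlid_norm",
                "alpha",
            ):
                row[f"{side}_{name}"] = getattr(m, name) if m else np.nan
            row[f"{side}_valid"] = bool(m.valid) if m else False
            row[f"{side}_reason"] = m.rejection_reason if m else "no_landmarks"
        rows.append(row)
    return pd.DataFrame(rows)


def _jsonable(obj):
    """numpy scalars → Python, NaN → None, recursively."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_outputs(out: Path, summary: dict, frames_df: pd.DataFrame, series):
    out.mkdir(parents=True, exist_ok=True)
    frames_df.to_csv(out / "frames.csv", index=False, float_format="%.6f")
    for name, s in series.items():
        grid = s.grid_timestamps
        in_gap = np.zeros(len(grid), dtype=bool)
        for start, end in s.gaps:
            in_gap |= (grid > start) & (grid < end)
        raw = np.full(len(grid), np.nan)
        if len(s.timestamps):
            # raw values only at actual sample times
            pos = np.searchsorted(s.timestamps, grid)
            pos = np.clip(pos, 0, len(s.timestamps) - 1)
            hit = np.abs(s.timestamps[pos] - grid) < 1e-9
            raw[hit] = s.values[pos[hit]]
        pd.DataFrame(
            {
                "timestamp": grid,
                "raw": raw,
                "interpolated": s.interpolated,
                "filtered": (
                    s.filtered if s.filtered is not None
                    else np.full(len(grid), np.nan)
                ),
                "in_gap": in_gap,
            }
        ).to_csv(out / f"series_{name}.csv", index=False, float_format="%.6f")
    (out / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n"
    )
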