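"""Pipeline configuration: every tunable threshold, with its default.

All numeric rules that the method leaves qualitative ("shrink until
convergence", "deviates significantly", "visible ptosis") are quantified
here and exposed through one dataclass that can be round-tripped to YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Every named threshold of the pipeline, config-file overridable.

    Units are pixels unless stated otherwise; ratios are dimensionless
    fractions of the eye length (EL) or of a baseline value.
    """

    # --- landmark localization validity -------------------------------
    #: eyes must sit in the upper half of the face box
    eye_lower_half_invalid: bool = True
    #: valid inter-ocular distance as a fraction of face-box width
    interocular_min_frac: float = 0.15
    interocular_max_frac: float = 0.8
    #: max tilt of the eye-center line from horizontal, degrees
    eye_line_max_tilt_deg: float = 25.0
    #: face box inflation when derived from the landmark bounding box
    face_box_inflate: float = 0.2

    # --- coarse metrics / blinks --------------------------------------
    #: EL below this is an under-resolved frame
    min_eye_length_px: float = 4.0
    #: blink = ED below this fraction of the rolling baseline
    blink_rel_threshold: float = 0.5
    #: rolling-median baseline window, seconds
    blink_baseline_window_s: float = 2.0
    #: maximum blink duration, seconds
    blink_max_duration_s: float = 0.5

    # --- local segmentation -------------------------------------------
    #: percentile stretch bounds for contrast enhancement
    stretch_lo_pct: float = 1.0
    stretch_hi_pct: float = 99.0
    #: lid rectangles padded vertically by this fraction of EL
    rect_pad_frac: float = 0.15
    #: minimum usable rectangle side
    min_rect_px: int = 4
    #: minimum k-means cluster separation score (between-centroid distance
    #: over pooled within-cluster std) for a usable clustering
    min_separation_score: float = 2.0
    #: fraction of ambiguous columns/rows that fails the interface
    max_ambiguous_frac: float = 0.2
    #: snake: curvature penalty weight and search band
    snake_lambda: float = 0.05
    snake_max_displacement_px: float = 3.0
    snake_max_iter: int = 50
    snake_tol_px: float = 0.1
    #: H1 smoothness: max per-step jump and total-variation fraction
    h1_max_step_px: float = 2.0
    h1_max_tv_frac: float = 0.5
    #: H3 convexity: max residual of the quadratic fit
    h3_max_residual_px: float = 2.0
    #: H4 connectedness: largest component must hold this label fraction
    h4_min_component_frac: float = 0.9
    #: clustering-vs-snake concurrence tolerance (the 2-pixel aim)
    concurrence_tol_px: float = 2.0
    #: retry schedule: re-seeds before each shrink, shrink factor, max shrinks
    reseed_attempts: int = 2
    shrink_factor: float = 0.8
    max_shrinks: int = 5

    # --- exam metrics --------------------------------------------------
    #: iris arcs subtending less than this angle give unreliable diameters
    iris_min_arc_deg: float = 60.0
    #: alpha values above this are flagged implausible
    alpha_max: float = 1.2
    #: misalignment flag threshold on |delta - baseline_delta|
    alpha_deviation_threshold: float = 0.05
    #: baseline window for the alpha delta, seconds
    alpha_baseline_window_s: float = 5.0
    #: droop onset = filtered lid opening below this fraction of initial
    droop_onset_frac: float = 0.9
    #: anatomic grade band around the pupil center, fraction of diameter
    pupil_band_frac: float = 0.25

    # --- timeseries -----------------------------------------------------
    #: gaps longer than this (seconds) are recorded, never interpolated
    max_interp_gap_s: float = 1.0
    #: spectral low-pass cutoff, Hz
    filter_cutoff_hz: float = 0.5
    #: minimum contiguous segment length to filter, seconds
    filter_min_segment_s: float = 4.0
    #: frame rejection: motion, landmark instability, face stillness
    motion_max_disp_frac: float = 0.1
    instability_jump_frac: float = 0.2
    instability_face_still_frac: float = 0.05
    #: gaze smoothing window (seconds) and minimum exercise run
    gaze_vote_window_s: float = 1.0
    min_exercise_run_s: float = 10.0
    #: neutral stretches (blinks, rest closures) up to this long do not
    #: split an exercise window
    window_bridge_s: float = 5.0
    #: nominal exercise duration bounds, seconds
    exercise_min_s: float = 40.0
    exercise_max_s: float = 80.0

    # --- reproducibility ------------------------------------------------
    base_seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


DEFAULT_CONFIG = PipelineConfig()
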