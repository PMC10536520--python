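"""Ground-truthed synthetic face/eye frames emulating telehealth acquisition.

The generator draws two eyes on a flat-skin background: each palpebral
aperture is bounded by parabolic upper/lower lid curves through the eye
corners, filled with sclera intensity, with an iris disk clipped to the
aperture.  A linear illumination ramp and per-frame Gaussian noise are
applied last.  Lid droop, blinks, sustained closures, gaze direction,
per-eye iris drift and whole-head jitter are all programmable, and every
frame exports its exact interface curves, landmark hexagons and scalar
metrics as ground truth — so each downstream stage can be validated to
sub-pixel precision without patient data.

Conditions emulated: frames as small as 450x800 at 30 FPS, eye apertures in
the ~10-45 px range, three intensity classes (skin, sclera, iris) with a
configurable contrast margin, the low-contrast/poor-lighting failure modes
of real telehealth video.  Not emulated: eyelashes, specular reflections,
compression artifacts, photorealistic shading.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

BLINK_HALF_WINDOW_S = 0.1  # blink closes and reopens over 0.2 s total
CLOSURE_RAMP_S = 0.1


@dataclass(frozen=True)
class SyntheticEyeSpec:
    """Full parameterization of a synthetic clip and its ground truth.

    Geometry is given for t=0 in image coordinates (origin top-left, y
    downward).  ``upper_lid_y``/``lower_lid_y`` are the lid apex rows at the
    eye center; the lids meet the corners at ``eye_center[1]``.
    ``droop_rate`` is the upper-lid descent in fractions of the initial
    palpebral aperture per second, so the relative lid-opening decay over a
    60 s exercise is ``60 * droop_rate``.
    """

    image_size: tuple[int, int] = (450, 800)  # (height, width)
    eye_centers: tuple[tuple[float, float], tuple[float, float]] = (
        (300.0, 225.0),
        (500.0, 225.0),
    )  # (x, y) right eye (image left), left eye (image right)
    eye_length: float = 60.0
    upper_lid_y: float = 210.0
    lower_lid_y: float = 240.0
    iris_radius: float = 16.0
    gaze: str = "up"  # {up, left, right, primary}
    #: mean gray levels in [0, 1]
    skin: float = 0.55
    sclera: float = 0.90
    iris: float = 0.15
    contrast_margin: float = 0.2
    noise_sigma: float = 0.02
    illum_gradient: float = 0.0  # gray level per pixel, horizontal ramp
    droop_rate: float = 0.0  # fraction of initial aperture per second
    blink_times: tuple[float, ...] = ()
    closure_intervals: tuple[tuple[float, float], ...] = ()
    iris_drift_px_s: tuple[float, float] = (0.0, 0.0)  # per-eye horizontal
    head_jitter_sigma: float = 0.0  # px, whole-geometry translation
    duration: float = 61.0
    fps: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.lower_lid_y <= self.upper_lid_y:
            raise ValueError("lower_lid_y must exceed upper_lid_y (y grows down)")
        if not (self.iris < self.sclera):
            raise ValueError("iris intensity must be darker than sclera")
        if abs(self.skin - self.sclera) < self.contrast_margin:
            raise ValueError(
                "skin/sclera contrast below the configured contrast margin"
            )
        if self.gaze not in ("up", "left", "right", "primary"):
            raise ValueError(f"unknown gaze {self.gaze!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))

    @property
    def aperture0(self) -> float:
        return self.lower_lid_y - self.upper_lid_y

    def iris_center0(self, eye: int) -> tuple[float, float]:
        """Iris center at t=0 for eye 0 (right) or 1 (left), set by gaze."""
        cx, cy = self.eye_centers[eye]
        ap = self.aperture0
        if self.gaze == "up":
            # iris raised so its bottom arc sits inside the aperture with
            # sclera visible below it (sustained up-gaze)
            return (cx, self.upper_lid_y + 0.1 * ap)
        if self.gaze == "primary":
            return (cx, cy)
        dx = 0.25 * self.eye_length
        return (cx - dx, cy) if self.gaze == "left" else (cx + dx, cy)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticEyeSpec":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("image_size", "blink_times", "iris_drift_px_s"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        if "eye_centers" in data:
            data["eye_centers"] = tuple(tuple(c) for c in data["eye_centers"])
        if "closure_intervals" in data:
            data["closure_intervals"] = tuple(
                tuple(c) for c in data["closure_intervals"]
            )
        return cls(**data)


@dataclass
class EyeTruth:
    """Exact per-eye geometry of one rendered frame (jitter included)."""

    side: str  # "right" or "left"
    cx: float
    cy: float
    eye_length: float
    upper_apex_y: float  # effective (droop + blink closure applied)
    lower_apex_y: float
    iris_cx: float
    iris_cy: float
    iris_radius: float

    def _lid(self, xs: np.ndarray, apex_y: float) -> np.ndarray:
        a = (np.asarray(xs, float) - self.cx) / (self.eye_length / 2.0)
        return self.cy + (apex_y - self.cy) * (1.0 - a**2)

    def upper_lid_curve(self, xs: np.ndarray) -> np.ndarray:
        return self._lid(xs, self.upper_apex_y)

    def lower_lid_curve(self, xs: np.ndarray) -> np.ndarray:
        return self._lid(xs, self.lower_apex_y)

    def iris_bottom_curve(self, xs: np.ndarray) -> np.ndarray:
        """Lower iris boundary y(x); NaN outside the chord."""
        xs = np.asarray(xs, float)
        d2 = self.iris_radius**2 - (xs - self.iris_cx) ** 2
        out = np.full_like(xs, np.nan, dtype=float)
        ok = d2 >= 0
        out[ok] = self.iris_cy + np.sqrt(d2[ok])
        return out

    def iris_lateral_curve(self, ys: np.ndarray, side: str) -> np.ndarray:
        """Lateral iris boundary x(y) on the given side ("left"/"right")."""
        ys = np.asarray(ys, float)
        d2 = self.iris_radius**2 - (ys - self.iris_cy) ** 2
        out = np.full_like(ys, np.nan, dtype=float)
        ok = d2 >= 0
        sgn = 1.0 if side == "right" else -1.0
        out[ok] = self.iris_cx + sgn * np.sqrt(d2[ok])
        return out

    @property
    def corners(self) -> tuple[tuple[float, float], tuple[float, float]]:
        h = self.eye_length / 2.0
        return ((self.cx - h, self.cy), (self.cx + h, self.cy))

    @property
    def hexagon(self) -> np.ndarray:
        """Six eye-contour points in the 68-point annotation order.

        Corner, two upper-lid points at the x thirds, corner, then the two
        lower-lid points walking back (matching indices 37-42 / 43-48).
        """
        (x0, cy), (x1, _) = self.corners
        third = self.eye_length / 3.0
        xa, xb = x0 + third, x0 + 2 * third
        return np.array(
            [
                [x0, cy],
                [xa, float(self.upper_lid_curve(np.array([xa]))[0])],
                [xb, float(self.upper_lid_curve(np.array([xb]))[0])],
                [x1, cy],
                [xb, float(self.lower_lid_curve(np.array([xb]))[0])],
                [xa, float(self.lower_lid_curve(np.array([xa]))[0])],
            ]
        )

    @property
    def ed(self) -> float:
        """Landmark eyelid distance: mean vertical gap at the x thirds."""
        hx = self.hexagon
        return float(((hx[5, 1] - hx[1, 1]) + (hx[4, 1] - hx[2, 1])) / 2.0)

    @property
    def area(self) -> float:
        hx = self.hexagon
        x, y = hx[:, 0], hx[:, 1]
        return float(
            abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0
        )

    def alpha(self, gaze: str) -> float:
        """Barycentric misalignment coordinate for lateral gaze, else NaN."""
        if gaze not in ("left", "right"):
            return float("nan")
        (x0, _), (x1, _) = self.corners
        if gaze == "left":
            p = self.iris_cx + self.iris_radius  # visible boundary, right side
            anchor = x1
        else:
            p = self.iris_cx - self.iris_radius
            anchor = x0
        return abs(p - anchor) / self.eye_length


@dataclass
class FrameTruth:
    frame_index: int
    t: float
    degenerate: bool
    in_blink: bool
    jitter: tuple[float, float]
    eyes: tuple[EyeTruth, EyeTruth]

    def row(self) -> dict:
        out = {
            "frame_index": self.frame_index,
            "t": self.t,
            "degenerate": self.degenerate,
            "in_blink": self.in_blink,
            "jitter_x": self.jitter[0],
            "jitter_y": self.jitter[1],
        }
        for eye in self.eyes:
            p = eye.side
            out.update(
                {
                    f"{p}_upper_lid_y": eye.upper_apex_y,
                    f"{p}_lower_lid_y": eye.lower_apex_y,
                    f"{p}_iris_bottom_y": eye.iris_cy + eye.iris_radius,
                    f"{p}_iris_cx": eye.iris_cx,
                    f"{p}_iris_cy": eye.iris_cy,
                    f"{p}_ed": eye.ed,
                    f"{p}_el": eye.eye_length,
                    f"{p}_area": eye.area,
                }
            )
        return out


def _closure(spec: SyntheticEyeSpec, t: float) -> tuple[float, bool]:
    """Lid-closure factor in [0,1] and whether t is in a blink window."""
    c = 0.0
    in_blink = False
    for tb in spec.blink_times:
        dt = abs(t - tb)
        if dt <= BLINK_HALF_WINDOW_S:
            c = max(c, 1.0 - dt / BLINK_HALF_WINDOW_S)
            in_blink = True
    for start, end in spec.closure_intervals:
        if start - CLOSURE_RAMP_S <= t <= end + CLOSURE_RAMP_S:
            if t < start:
                c = max(c, 1.0 - (start - t) / CLOSURE_RAMP_S)
            elif t > end:
                c = max(c, 1.0 - (t - end) / CLOSURE_RAMP_S)
            else:
                c = 1.0
            in_blink = True
    return c, in_blink


def frame_truth(
    spec: SyntheticEyeSpec, t: float, jitter: tuple[float, float] = (0.0, 0.0)
) -> FrameTruth:
    """Exact geometry at time t with an explicit whole-head translation."""
    c, in_blink = _closure(spec, t)
    dx, dy = jitter
    drop = spec.droop_rate * t * spec.aperture0
    eyes = []
    for i, side in enumerate(("right", "left")):
        cx, cy = spec.eye_centers[i]
        upper = spec.upper_lid_y + drop
        lower = spec.lower_lid_y
        upper_eff = upper + c * (lower - upper)  # blink: upper lid closes down
        ix, iy = spec.iris_center0(i)
        ix = ix + spec.iris_drift_px_s[i] * t
        eyes.append(
            EyeTruth(
                side=side,
                cx=cx + dx,
                cy=cy + dy,
                eye_length=spec.eye_length,
                upper_apex_y=upper_eff + dy,
                lower_apex_y=lower + dy,
                iris_cx=ix + dx,
                iris_cy=iy + dy,
                iris_radius=spec.iris_radius,
            )
        )
    degenerate = eyes[0].upper_apex_y >= eyes[0].lower_apex_y and not in_blink
    idx = int(round(t * spec.fps))
    return FrameTruth(
        frame_index=idx,
        t=t,
        degenerate=degenerate,
        in_blink=in_blink,
        jitter=jitter,
        eyes=(eyes[0], eyes[1]),
    )


def render_frame(
    spec: SyntheticEyeSpec,
    t: float,
    jitter: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, FrameTruth]:
    """Render one grayscale frame in [0,1] plus its ground truth.

    Drawing order: skin background, scleral aperture between the lid
    curves, iris disk clipped to the aperture, illumination ramp, noise.
    A fully closed aperture outside a blink window is rendered anyway and
    flagged degenerate in the truth record.
    """
    if not (0.0 <= t <= spec.duration):
        raise ValueError(f"t={t} outside [0, {spec.duration}]")
    truth = frame_truth(spec, t, jitter)
    h, w = spec.image_size
    img = np.full((h, w), spec.skin, dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]
    for eye in truth.eyes:
        half = eye.eye_length / 2.0
        a = (xx - eye.cx) / half
        inside = np.abs(a) <= 1.0
        shape = 1.0 - np.clip(a, -1.0, 1.0) ** 2
        yu = eye.cy + (eye.upper_apex_y - eye.cy) * shape
        yl = eye.cy + (eye.lower_apex_y - eye.cy) * shape
        aperture = inside & (yy >= yu) & (yy <= yl)
        img[aperture] = spec.sclera
        iris = aperture & (
            (xx - eye.iris_cx) ** 2 + (yy - eye.iris_cy) ** 2
            <= eye.iris_radius**2
        )
        img[iris] = spec.iris
    if spec.illum_gradient != 0.0:
        img = img + spec.illum_gradient * (xx - w / 2.0)
    if spec.noise_sigma > 0.0:
        rng = np.random.default_rng([spec.seed, truth.frame_index])
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0), truth


def make_eye_spec(
    eye_length: float = 60.0,
    aperture_frac: float = 0.5,
    iris_frac: float = 0.53,
    **overrides,
) -> SyntheticEyeSpec:
    """Spec with all eye geometry scaled proportionally to the eye length.

    ``aperture_frac`` is the palpebral aperture height and ``iris_frac``
    the iris diameter, both as fractions of EL; eye centers and image size
    keep their defaults unless overridden.
    """
    cy = 225.0
    ap = aperture_frac * eye_length
    defaults = dict(
        eye_length=eye_length,
        upper_lid_y=cy - ap / 2.0,
        lower_lid_y=cy + ap / 2.0,
        iris_radius=iris_frac * eye_length / 2.0,
    )
    defaults.update(overrides)
    return SyntheticEyeSpec(**defaults)


def sequence_jitters(spec: SyntheticEyeSpec) -> np.ndarray:
    """Per-frame head-jitter translations (n_frames, 2), seed-determined."""
    n = spec.n_frames
    if spec.head_jitter_sigma <= 0:
        return np.zeros((n, 2))
    rng = np.random.default_rng([spec.seed, 74])  # jitter stream
    return rng.normal(0.0, spec.head_jitter_sigma, size=(n, 2))


def render_sequence(
    spec: SyntheticEyeSpec,
) -> Iterator[tuple[np.ndarray, FrameTruth]]:
    """Yield duration*fps frames with per-frame head jitter applied.

    Jitter is a seeded Gaussian translation of the whole eye geometry,
    drawn independently per frame; deterministic for a fixed spec seed.
    """
    n = spec.n_frames
    if n < 1:
        raise ValueError("duration * fps must be >= 1")
    jitters = sequence_jitters(spec)
    for i in range(n):
        t = i / spec.fps
        frame, truth = render_frame(spec, t, jitter=tuple(jitters[i]))
        truth.frame_index = i
        yield frame, truth


def sequence_truth_table(spec: SyntheticEyeSpec) -> pd.DataFrame:
    """Ground-truth table (no rendering) for every frame of the sequence."""
    rows = []
    n = spec.n_frames
    jitters = sequence_jitters(spec)
    for i in range(n):
        truth = frame_truth(spec, i / spec.fps, jitter=tuple(jitters[i]))
        truth.frame_index = i
        row = truth.row()
        for eye in truth.eyes:
            row[f"{eye.side}_alpha"] = eye.alpha(spec.gaze)
        rows.append(row)
    return pd.DataFrame(rows)


def write_clip(spec: SyntheticEyeSpec, out_dir: str | Path) -> Path:
    """Write a clip as 8-bit gray PNG frames + manifest + truth CSV + spec.

    Returns the clip directory, readable by :func:`oculid.io.read_frames`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for frame, truth in render_sequence(spec):
        png = (np.clip(frame, 0, 1) * 255).round().astype(np.uint8)
        iio.imwrite(out / f"frame_{truth.frame_index:05d}.png", png)
        row = truth.row()
        for eye in truth.eyes:
            row[f"{eye.side}_alpha"] = eye.alpha(spec.gaze)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "truth.csv", index=False)
    (out / "manifest.yaml").write_text(
        yaml.safe_dump({"fps": spec.fps, "n_frames": spec.n_frames})
    )
    spec.to_yaml(out / "spec.yaml")
    return out
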