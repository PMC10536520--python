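"""68-point facial landmarks: providers, per-eye hexagon ROIs, validity.

Landmark indices are 1-based throughout logs and configuration, following
the standard 68-point facial annotation: points 37-42 outline the right
eye and 43-48 the left eye.  The landmark model itself is an external,
pluggable component (an adapter around a face-alignment library); the
fixture provider returns synthetic ground-truth landmarks, optionally
perturbed to emulate provider bias, so the downstream pipeline behaves
identically for either source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from oculid.config import DEFAULT_CONFIG, PipelineConfig
from oculid.synthetic import FrameTruth, SyntheticEyeSpec, frame_truth

#: 1-based annotation indices of the eye contours
RIGHT_EYE_INDICES = (37, 38, 39, 40, 41, 42)
LEFT_EYE_INDICES = (43, 44, 45, 46, 47, 48)


class ConfigurationError(RuntimeError):
    """A provider or option is misconfigured (distinct from 'no face')."""


@dataclass
class LandmarkSet:
    """68 facial landmarks for one frame, continuous pixel coordinates."""

    points: np.ndarray  # (68, 2) float, columns (x, y), origin top-left
    frame_index: int = 0
    timestamp: float = 0.0
    source: str = "fixture"  # {external_model, fixture}

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (68, 2):
            raise ValueError(f"expected (68, 2) points, got {self.points.shape}")

    def point(self, index_1based: int) -> np.ndarray:
        return self.points[index_1based - 1]

    def in_bounds(self, image_size: tuple[int, int]) -> bool:
        """All points inside the (height, width) image rectangle."""
        h, w = image_size
        x, y = self.points[:, 0], self.points[:, 1]
        return bool(
            np.all((x >= 0) & (x <= w - 1) & (y >= 0) & (y <= h - 1))
        )


@dataclass
class EyeHexagon:
    """The six eye-contour landmarks, in annotation order.

    Order: temporal-side corner, two upper-lid points, nasal-side corner,
    two lower-lid points walking back (indices 37..42 / 43..48).
    """

    side: str  # {right, left}
    vertices: np.ndarray  # (6, 2)
    degenerate: bool = False

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.shape != (6, 2):
            raise ValueError("hexagon needs 6 vertices")
        # degenerates to a pentagon when two vertices coincide within 1 px
        d = np.linalg.norm(
            self.vertices[:, None, :] - self.vertices[None, :, :], axis=-1
        )
        iu = np.triu_indices(6, k=1)
        self.degenerate = bool(np.any(d[iu] < 1.0))

    @property
    def center(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def corner_temporal(self) -> np.ndarray:
        return self.vertices[0]

    @property
    def corner_nasal(self) -> np.ndarray:
        return self.vertices[3]

    @property
    def upper(self) -> np.ndarray:
        return self.vertices[1:3]

    @property
    def lower(self) -> np.ndarray:
        """Lower-lid points reordered to pair vertically with ``upper``."""
        return self.vertices[[5, 4]]

    def bounding_box(self, pad: float = 0.0) -> tuple[float, float, float, float]:
        x0, y0 = self.vertices.min(axis=0) - pad
        x1, y1 = self.vertices.max(axis=0) + pad
        return (float(x0), float(y0), float(x1), float(y1))


def extract_eye_hexagons(lm: LandmarkSet) -> tuple[EyeHexagon, EyeHexagon]:
    """Right (points 37-42) and left (43-48) eye hexagons."""
    right = EyeHexagon(
        "right", np.stack([lm.point(i) for i in RIGHT_EYE_INDICES])
    )
    left = EyeHexagon(
        "left", np.stack([lm.point(i) for i in LEFT_EYE_INDICES])
    )
    return right, left


def face_box_from_landmarks(
    lm: LandmarkSet, inflate: float = DEFAULT_CONFIG.face_box_inflate
) -> tuple[float, float, float, float]:
    """Landmark bounding box inflated by a fraction on every side.

    Used when the provider gives landmarks without a detector face box.
    """
    x0, y0 = lm.points.min(axis=0)
    x1, y1 = lm.points.max(axis=0)
    mx, my = inflate * (x1 - x0), inflate * (y1 - y0)
    return (float(x0 - mx), float(y0 - my), float(x1 + mx), float(y1 + my))


def validate_eye_localization(
    right: EyeHexagon,
    left: EyeHexagon,
    face_box: tuple[float, float, float, float],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[bool, str]:
    """Geometric sanity check on the eye ROIs against the face box.

    Catches gross mislocalizations (e.g. a landmark model latching onto
    the nostrils): eye centers in the lower half of the face box, an
    implausible inter-ocular distance, or a strongly tilted eye line.
    Returns (valid, reason); reason is "" when valid.
    """
    x0, y0, x1, y1 = face_box
    width = x1 - x0
    mid_y = (y0 + y1) / 2.0
    rc, lc = right.center, left.center
    if config.eye_lower_half_invalid and (rc[1] > mid_y or lc[1] > mid_y):
        return False, "below mid-face"
    dist = float(np.linalg.norm(lc - rc))
    if width <= 0 or not (
        config.interocular_min_frac * width
        <= dist
        <= config.interocular_max_frac * width
    ):
        return False, "interocular distance out of range"
    tilt = np.degrees(np.arctan2(abs(lc[1] - rc[1]), abs(lc[0] - rc[0]) + 1e-12))
    if tilt > config.eye_line_max_tilt_deg:
        return False, "eye line tilted"
    return True, ""


# ---------------------------------------------------------------------------
# providers
# ---------------------------------------------------------------------------


def full_face_landmarks(
    truth: FrameTruth, image_size: tuple[int, int] | None = None
) -> np.ndarray:
    """A complete 68-point layout consistent with the synthetic eye truth.

    Eye points (37-48) are the exact hexagon vertices; the remaining 56
    points form a plausible face scaffold (jaw, brows, nose, mouth) scaled
    to the inter-ocular distance — enough for face-box derivation and
    localization-validity checks, not for rendering.  When ``image_size``
    is given, scaffold points are clamped into the frame, as with a
    close-up face partially cropped by the camera.
    """
    right, left = truth.eyes
    rc = np.array([right.cx, right.cy])
    lc = np.array([left.cx, left.cy])
    m = (rc + lc) / 2.0
    d = float(np.linalg.norm(lc - rc))
    pts = np.zeros((68, 2))
    # jaw (1-17): half ellipse from right temple through chin to left temple
    th = np.linspace(np.pi, 2 * np.pi, 17)
    pts[0:17, 0] = m[0] + 1.2 * d * np.cos(th)
    pts[0:17, 1] = m[1] + np.abs(np.sin(th)) * 1.8 * d
    # brows (18-27)
    for k, (c, sgn) in enumerate(((rc, -1), (lc, 1))):
        xs = c[0] + np.linspace(-0.35, 0.35, 5) * d
        pts[17 + 5 * k : 22 + 5 * k, 0] = xs
        pts[17 + 5 * k : 22 + 5 * k, 1] = c[1] - 0.35 * d
    # nose bridge (28-31) and base (32-36); 32/36 approximate the nostrils
    pts[27:31, 0] = m[0]
    pts[27:31, 1] = m[1] + np.linspace(0.0, 0.55, 4) * d
    pts[31:36, 0] = m[0] + np.linspace(-0.25, 0.25, 5) * d
    pts[31:36, 1] = m[1] + 0.65 * d
    # eyes (37-48): exact truth hexagons
    pts[36:42] = right.hexagon
    pts[42:48] = left.hexagon
    # mouth (49-68): outer 12 + inner 8 ellipse
    th = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    pts[48:60, 0] = m[0] + 0.45 * d * np.cos(th)
    pts[48:60, 1] = m[1] + 1.15 * d + 0.18 * d * np.sin(th)
    th = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    pts[60:68, 0] = m[0] + 0.3 * d * np.cos(th)
    pts[60:68, 1] = m[1] + 1.15 * d + 0.1 * d * np.sin(th)
    if image_size is not None:
        h, w = image_size
        scaffold = np.ones(68, dtype=bool)
        scaffold[36:48] = False  # never move the eye points
        pts[scaffold, 0] = np.clip(pts[scaffold, 0], 1.0, w - 2.0)
        pts[scaffold, 1] = np.clip(pts[scaffold, 1], 1.0, h - 2.0)
    return pts


@dataclass
class FixtureLandmarkProvider:
    """Ground-truth landmark provider for synthetic clips.

    ``bias`` maps 1-based landmark indices to (dx, dy) pixel offsets,
    emulating systematic provider error (e.g. lower-lid points 41-42
    placed below the true contour); ``noise_sigma`` adds seeded Gaussian
    scatter to every point.
    """

    spec: SyntheticEyeSpec
    bias: dict[int, tuple[float, float]] = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int = 0
    jitters: np.ndarray | None = None  # (n, 2) per-frame head translation

    def _jitter(self, frame_index: int) -> tuple[float, float]:
        if self.jitters is not None and 0 <= frame_index < len(self.jitters):
            return tuple(self.jitters[frame_index])
        if self.spec.head_jitter_sigma > 0:
            rng = np.random.default_rng([self.spec.seed, 74])
            jit = rng.normal(
                0.0, self.spec.head_jitter_sigma, size=(self.spec.n_frames, 2)
            )
            self.jitters = jit
            return tuple(jit[frame_index])
        return (0.0, 0.0)

    def __call__(
        self, frame: np.ndarray | None, frame_index: int = 0, timestamp: float = 0.0
    ) -> LandmarkSet | None:
        truth = frame_truth(
            self.spec, timestamp, jitter=self._jitter(frame_index)
        )
        pts = full_face_landmarks(truth, image_size=self.spec.image_size)
        for idx, (dx, dy) in self.bias.items():
            pts[idx - 1] += (dx, dy)
        if self.noise_sigma > 0:
            rng = np.random.default_rng([self.seed, frame_index, 68])
            pts = pts + rng.normal(0.0, self.noise_sigma, size=pts.shape)
        return LandmarkSet(
            points=pts,
            frame_index=frame_index,
            timestamp=timestamp,
            source="fixture",
        )


class ExternalLandmarkProvider:
    """Adapter around an external face-alignment backend (e.g. dlib).

    The detector/predictor are external, untrained-here components; this
    class only normalizes their output to :class:`LandmarkSet`.  Raises
    :class:`ConfigurationError` when the backend or its model file is
    unavailable — deliberately distinct from returning ``None`` (no face
    found in the frame).
    """

    def __init__(self, predictor_path: str | None = None):
        try:
            import dlib  # type: ignore
        except ImportError as exc:  # pragma: no cover - backend optional
            raise ConfigurationError(
                "external landmark backend 'dlib' is not installed; use the "
                "fixture provider or precomputed --landmarks CSV"
            ) from exc
        if predictor_path is None:
            raise ConfigurationError(
                "a 68-point shape-predictor model path is required"
            )
        self._detector = dlib.get_frontal_face_detector()
        self._predictor = dlib.shape_predictor(predictor_path)

    def __call__(
        self, frame: np.ndarray, frame_index: int = 0, timestamp: float = 0.0
    ) -> LandmarkSet | None:  # pragma: no cover - backend optional
        img = np.ascontiguousarray(
            (np.clip(frame, 0, 1) * 255).astype(np.uint8)
            if frame.dtype.kind == "f"
            else frame
        )
        faces = self._detector(img)
        if len(faces) == 0:
            return None
        shape = self._predictor(img, faces[0])
        pts = np.array([[p.x, p.y] for p in shape.parts()], dtype=float)
        return LandmarkSet(
            points=pts,
            frame_index=frame_index,
            timestamp=timestamp,
            source="external_model",
        )


# ---------------------------------------------------------------------------
# landmark files (CSV per clip)
# ---------------------------------------------------------------------------


def write_landmarks_csv(sets: list[LandmarkSet], path: str | Path) -> None:
    """One row per frame: frame_index, timestamp, x1,y1,...,x68,y68."""
    cols = {"frame_index": [s.frame_index for s in sets],
            "timestamp": [s.timestamp for s in sets]}
    arr = np.stack([s.points for s in sets]) if sets else np.zeros((0, 68, 2))
    for i in range(68):
        cols[f"x{i + 1}"] = arr[:, i, 0]
        cols[f"y{i + 1}"] = arr[:, i, 1]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_landmarks_csv(path: str | Path) -> list[LandmarkSet]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        pts = np.array(
            [[row[f"x{i + 1}"], row[f"y{i + 1}"]] for i in range(68)]
        )
        out.append(
            LandmarkSet(
                points=pts,
                frame_index=int(row["frame_index"]),
                timestamp=float(row["timestamp"]),
                source="fixture",
            )
        )
    return out
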