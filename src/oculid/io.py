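"""Clip ingestion and debug-overlay output.

A clip is either a video file readable by imageio or a directory of still
frames (PNG/JPEG) with a ``manifest.yaml`` giving the frame rate.  Frames
are yielded in temporal order as grayscale float images in [0, 1], with
timestamps ``frame_index / fps``, optionally subsampled every k seconds
or every Nth frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from oculid.landmarks import ConfigurationError

FRAME_PATTERNS = ("*.png", "*.jpg", "*.jpeg")


@dataclass
class ClipDescriptor:
    """Where a clip lives and how to sample it."""

    source: str | Path
    fps: float | None = None
    exercise_hint: str | None = None  # {ptosis, diplopia}
    frame_range: tuple[int, int] | None = None  # half-open frame indices
    sample_every_s: float | None = None
    sample_every_n: int | None = None

    def step(self, fps: float) -> int:
        if self.sample_every_s is not None:
            step = int(round(self.sample_every_s * fps))
            if step < 1:
                raise ValueError("sampling interval below one frame period")
            return step
        if self.sample_every_n is not None:
            if self.sample_every_n < 1:
                raise ValueError("sample_every_n must be >= 1")
            return self.sample_every_n
        return 1


def _to_gray(frame: np.ndarray) -> np.ndarray:
    arr = np.asarray(frame)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.dtype.kind in "ui":
        arr = arr.astype(np.float64) / 255.0
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def read_frames(
    clip: ClipDescriptor,
) -> Iterator[tuple[int, float, np.ndarray]]:
    """Yield (frame_index, timestamp, gray image) applying the sampling.

    Raises OSError for an unreadable/empty source and
    :class:`ConfigurationError` when no frame rate can be determined.
    """
    src = Path(clip.source)
    if src.is_dir():
        yield from _read_frame_dir(clip, src)
    else:
        yield from _read_video(clip, src)


def _read_frame_dir(clip: ClipDescriptor, src: Path):
    import imageio.v3 as iio

    files: list[Path] = []
    for pat in FRAME_PATTERNS:
        files.extend(src.glob(pat))
    files = sorted(files)
    if not files:
        raise OSError(f"no frames found in {src}")
    fps = clip.fps
    manifest = src / "manifest.yaml"
    if fps is None and manifest.exists():
        fps = float(yaml.safe_load(manifest.read_text()).get("fps", 0) or 0)
    if not fps or fps <= 0:
        raise ConfigurationError("frame rate unknown: pass fps or a manifest")
    step = clip.step(fps)
    lo, hi = clip.frame_range or (0, len(files))
    for i in range(lo, min(hi, len(files)), step):
        yield i, i / fps, _to_gray(iio.imread(files[i]))


def _read_video(clip: ClipDescriptor, src: Path):
    import imageio.v3 as iio

    if not src.exists():
        raise OSError(f"clip not found: {src}")
    fps = clip.fps
    if fps is None:
        try:
            meta = iio.immeta(src, exclude_applied=False)
            fps = float(meta.get("fps", 0) or 0)
        except Exception:
            fps = 0.0
    if not fps or fps <= 0:
        raise ConfigurationError("frame rate unknown: pass fps explicitly")
    step = clip.step(fps)
    lo, hi = clip.frame_range or (0, None)
    try:
        it = iio.imiter(src)
    except Exception as exc:
        raise OSError(f"cannot decode {src}: {exc}") from exc
    for i, frame in enumerate(it):
        if i < lo or (hi is not None and i >= hi):
            continue
        if (i - lo) % step == 0:
            yield i, i / fps, _to_gray(frame)


def write_overlay(
    image: np.ndarray,
    rectangles: list,
    curves: list,
    landmarks: np.ndarray | None,
    path: str | Path,
) -> None:
    """Debug PNG: search rectangles (blue), accepted curves (green),
    landmarks (red) over the frame."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5), dpi=110)
    ax.imshow(image, cmap="gray", vmin=0, vmax=1)
    for rect in rectangles:
        x0, y0, x1, y1 = rect.bounds
        ax.plot(
            [x0, x1, x1, x0, x0], [y0, y0, y1, y1, y0], color="#2060ff", lw=0.8
        )
    for curve in curves:
        if curve is None:
            continue
        if curve.crossing_axis == "horizontal":
            ax.plot(curve.axis_values, curve.samples, color="#00c040", lw=1.2)
        else:
            ax.plot(curve.samples, curve.axis_values, color="#00c040", lw=1.2)
    if landmarks is not None:
        ax.plot(landmarks[:, 0], landmarks[:, 1], "r.", ms=2)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)
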