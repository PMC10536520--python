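"""Hypothesis-validated interface segmentation inside landmark rectangles.

Each anatomic interface (upper lid, lower lid, iris bottom, lateral iris
boundary) is searched for inside a small rectangle placed from the eye
hexagon, in a divide-and-conquer fashion: the patch is contrast-enhanced,
partitioned into two intensity clusters, the cluster boundary is turned
into a single-valued curve, refined by an open snake that maximizes the
image gradient along it, and accepted only when the validity hypotheses
hold:

  H1  the curve is smooth (bounded per-step jump and total variation);
  H2  it crosses the rectangle fully, one sample per column (or row);
  H3  iris arcs are convex, bulging into the sclera;
  H4  each intensity cluster is a connected pixel set.

On failure the clustering is re-seeded, then the rectangle is shrunk about
its anchor landmark until an acceptable interface is found or the search
is exhausted, in which case the frame is skipped for that interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from oculid.config import DEFAULT_CONFIG, PipelineConfig
from oculid.landmarks import EyeHexagon

HORIZONTAL = "horizontal"  # curve is y(x), one sample per column
VERTICAL = "vertical"  # curve is x(y), one sample per row


@dataclass
class SearchRectangle:
    """Integer half-open pixel rectangle [x0,x1) x [y0,y1) with a target."""

    bounds: tuple[int, int, int, int]  # x0, y0, x1, y1
    target: str  # {lower_lid, upper_lid, iris_bottom, iris_lateral}
    crossing_axis: str  # HORIZONTAL for lids/iris bottom, VERTICAL lateral
    anchor: tuple[float, float]  # shrink anchor (target landmark point)
    shrink_level: int = 0

    @property
    def width(self) -> int:
        return self.bounds[2] - self.bounds[0]

    @property
    def height(self) -> int:
        return self.bounds[3] - self.bounds[1]

    @property
    def area(self) -> int:
        return self.width * self.height

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.bounds
        return x0 <= x < x1 and y0 <= y < y1

    def patch(self, image: np.ndarray) -> np.ndarray:
        x0, y0, x1, y1 = self.bounds
        return image[y0:y1, x0:x1]

    def shrunk(self, factor: float, min_px: int) -> "SearchRectangle | None":
        """Smaller rectangle about the anchor; None below the minimum size."""
        x0, y0, x1, y1 = self.bounds
        ax, ay = self.anchor
        ax = min(max(ax, x0 + 1), x1 - 1)
        ay = min(max(ay, y0 + 1), y1 - 1)
        hw, hh = self.width * factor / 2.0, self.height * factor / 2.0
        nx0, nx1 = int(round(ax - hw)), int(round(ax + hw))
        ny0, ny1 = int(round(ay - hh)), int(round(ay + hh))
        # stay inside the parent rectangle and keep the anchor interior
        nx0, ny0 = max(nx0, x0), max(ny0, y0)
        nx1, ny1 = min(nx1, x1), min(ny1, y1)
        if nx1 - nx0 < min_px or ny1 - ny0 < min_px:
            return None
        return SearchRectangle(
            bounds=(nx0, ny0, nx1, ny1),
            target=self.target,
            crossing_axis=self.crossing_axis,
            anchor=(ax, ay),
            shrink_level=self.shrink_level + 1,
        )


@dataclass
class InterfaceCurve:
    """Single-valued interface curve across a rectangle, frame coordinates.

    For a horizontal crossing, ``axis_values`` are the column x positions
    and ``samples`` the sub-pixel interface rows y(x); for a vertical
    crossing, rows y and columns x(y) respectively.
    """

    axis_values: np.ndarray
    samples: np.ndarray
    crossing_axis: str
    method: str = "clustering"  # {clustering, snake}
    ambiguous: np.ndarray | None = None
    quality: dict = field(default_factory=dict)
    accepted: bool = False
    flags: list = field(default_factory=list)

    def value_at(self, coord: float) -> float:
        return float(np.interp(coord, self.axis_values, self.samples))


@dataclass
class SegmentationOutcome:
    curve: InterfaceCurve | None
    attempts: int
    final_rectangle: SearchRectangle
    failure_reason: str = "none"  # {none, contrast, hypothesis, exhausted}
    #: hypothesis record of the last evaluated candidate (also on failure);
    #: a failed H4 here signals non-connex clusters, i.e. lighting trouble
    last_quality: dict | None = None

    @property
    def accepted(self) -> bool:
        return self.curve is not None and self.failure_reason == "none"


# ---------------------------------------------------------------------------
# rectangle construction
# ---------------------------------------------------------------------------


def _clip_rect(
    x0: float, y0: float, x1: float, y1: float, image_size: tuple[int, int]
) -> tuple[int, int, int, int]:
    h, w = image_size
    return (
        int(max(0, np.floor(x0))),
        int(max(0, np.floor(y0))),
        int(min(w, np.ceil(x1))),
        int(min(h, np.ceil(y1))),
    )


def build_rectangles(
    hexagon: EyeHexagon,
    exercise: str,
    gaze: str = "up",
    image_size: tuple[int, int] = (450, 800),
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[SearchRectangle]:
    """Search rectangles for one eye, per exercise.

    Ptosis: a rectangle around the lower-lid segment (points 41-42 /
    47-48) padded vertically by ±``rect_pad_frac``·EL, one around the
    upper-lid segment (38-39 / 44-45), and an iris-bottom rectangle
    spanning the upper-segment x range from the upper-lid level down to
    the lower-lid level.  Diplopia adds a lateral box that starts at the
    eye corner opposite the gaze direction and extends to the upper/lower
    lid landmarks on the far side, crossed vertically by the iris
    boundary.  Rectangles are clipped to the image; those falling below
    the minimum size are omitted.
    """
    if hexagon.degenerate:
        raise ValueError("cannot build rectangles from a degenerate hexagon")
    v = hexagon.vertices
    el = abs(float(v[3, 0] - v[0, 0]))
    if el < config.min_eye_length_px:
        raise ValueError("eye length under-resolved")
    pad = config.rect_pad_frac * el
    upper, lower = v[1:3], v[[5, 4]]
    rects: list[SearchRectangle] = []

    def add(x0, y0, x1, y1, target, axis, anchor):
        b = _clip_rect(x0, y0, x1, y1, image_size)
        if b[2] - b[0] >= config.min_rect_px and b[3] - b[1] >= config.min_rect_px:
            rects.append(
                SearchRectangle(bounds=b, target=target, crossing_axis=axis,
                                anchor=anchor)
            )

    # lower lid: around segment 41-42 (vertices 4,5)
    seg = v[4:6]
    add(
        seg[:, 0].min(), seg[:, 1].min() - pad,
        seg[:, 0].max(), seg[:, 1].max() + pad,
        "lower_lid", HORIZONTAL, tuple(seg.mean(axis=0)),
    )
    # upper lid: around segment 38-39 (vertices 1,2)
    seg = v[1:3]
    add(
        seg[:, 0].min(), seg[:, 1].min() - pad,
        seg[:, 0].max(), seg[:, 1].max() + pad,
        "upper_lid", HORIZONTAL, tuple(seg.mean(axis=0)),
    )
    if exercise == "ptosis":
        # iris bottom: x range of the upper segment, from the upper-lid
        # level down to the lower-lid level (contains 38, 39, 40, 41)
        x0, x1 = upper[:, 0].min(), upper[:, 0].max()
        y0, y1 = upper[:, 1].min(), lower[:, 1].max()
        add(x0, y0, x1, y1, "iris_bottom", HORIZONTAL,
            ((x0 + x1) / 2.0, (y0 + y1) / 2.0))
    elif exercise == "diplopia":
        if gaze == "left":
            corner = v[np.argmax(v[:, 0])]  # corner away from gaze
            xa = min(upper[:, 0].min(), lower[:, 0].min())
            x0, x1 = xa, corner[0]
        elif gaze == "right":
            corner = v[np.argmin(v[:, 0])]
            xb = max(upper[:, 0].max(), lower[:, 0].max())
            x0, x1 = corner[0], xb
        else:
            raise ValueError("diplopia requires gaze 'left' or 'right'")
        y0 = upper[:, 1].min()
        y1 = lower[:, 1].max()
        # the visible iris boundary lies toward the far-from-corner end of
        # the box; anchoring the shrink a quarter of the way from that end
        # sheds the skin wedges at the corner while keeping it in view
        if gaze == "left":
            ax = x0 + 0.25 * (x1 - x0)
        else:
            ax = x1 - 0.25 * (x1 - x0)
        add(x0, y0, x1, y1, "iris_lateral", VERTICAL, (ax, (y0 + y1) / 2.0))
    else:
        raise ValueError(f"unknown exercise {exercise!r}")
    return rects


# ---------------------------------------------------------------------------
# per-patch primitives
# ---------------------------------------------------------------------------


def enhance_contrast(
    patch: np.ndarray, config: PipelineConfig = DEFAULT_CONFIG
) -> tuple[np.ndarray, bool]:
    """Percentile stretch to [0,1]; flags a zero-dynamic-range patch."""
    if patch.shape[0] < 4 or patch.shape[1] < 4:
        raise ValueError("patch must be at least 4x4")
    lo = np.percentile(patch, config.stretch_lo_pct)
    hi = np.percentile(patch, config.stretch_hi_pct)
    if hi - lo <= 1e-12:
        return patch.astype(float), True
    return np.clip((patch - lo) / (hi - lo), 0.0, 1.0), False


def segment_two_cluster(
    patch: np.ndarray, seed: int, config: PipelineConfig = DEFAULT_CONFIG
) -> tuple[np.ndarray, float]:
    """Two-cluster intensity partition by seeded Lloyd iteration.

    Returns (labels, separation score); label 1 is the brighter cluster.
    The separation score is the centroid distance over the pooled
    within-cluster standard deviation.  Deterministic for a fixed seed.
    Raises ValueError on a zero-dynamic-range patch.
    """
    v = np.asarray(patch, dtype=float).ravel()
    if v.size < 16:
        raise ValueError("patch too small for clustering")
    if v.max() - v.min() <= 1e-12:
        raise ValueError("zero dynamic range")
    rng = np.random.default_rng(seed if seed >= 0 else None)
    c = np.sort(rng.choice(v, size=2, replace=False))
    for _ in range(16):
        if c[1] - c[0] > 1e-12:
            break
        c = np.sort(rng.choice(v, size=2, replace=False))
    else:
        c = np.array([v.min(), v.max()])
    for _ in range(100):
        lab = (np.abs(v - c[1]) < np.abs(v - c[0])).astype(np.uint8)
        if lab.all() or not lab.any():
            # empty cluster: reinitialize at the extremes
            c = np.array([v.min(), v.max()])
            continue
        new = np.array([v[lab == 0].mean(), v[lab == 1].mean()])
        if np.allclose(new, c, atol=1e-12):
            c = new
            break
        c = new
    lab = (np.abs(v - c[1]) < np.abs(v - c[0])).astype(np.uint8)
    if c[1] < c[0]:  # label 1 = brighter
        lab = 1 - lab
        c = c[::-1]
    n0, n1 = (lab == 0).sum(), (lab == 1).sum()
    var0 = v[lab == 0].var() if n0 else 0.0
    var1 = v[lab == 1].var() if n1 else 0.0
    pooled = np.sqrt((n0 * var0 + n1 * var1) / max(n0 + n1, 1))
    sep = abs(c[1] - c[0]) / max(pooled, 1e-9)
    return lab.reshape(patch.shape), float(sep)


def _majority_filter(labels: np.ndarray) -> np.ndarray:
    """3x3 majority vote on a binary label field (suppresses salt noise)."""
    return (ndimage.uniform_filter(labels.astype(float), size=3) > 0.5).astype(
        np.uint8
    )


def labels_to_interface(
    labels: np.ndarray,
    axis: str,
    rect: SearchRectangle,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> InterfaceCurve | None:
    """Cluster boundary as a single-valued sub-pixel curve, pre-validation.

    Per column (row, for vertical crossing): after a 3x3 majority cleanup,
    a column with exactly two label runs gives the interface at the
    midpoint between them; any other run structure marks the column
    ambiguous (filled by interpolation, recorded in the mask).  More than
    ``max_ambiguous_frac`` ambiguous columns aborts (returns None).
    """
    lab = _majority_filter(labels)
    work = lab if axis == HORIZONTAL else lab.T
    n_lines = work.shape[1]
    samples = np.full(n_lines, np.nan)
    ambiguous = np.zeros(n_lines, dtype=bool)
    for j in range(n_lines):
        col = work[:, j]
        change = np.flatnonzero(np.diff(col.astype(np.int8)) != 0)
        if len(change) == 1:
            samples[j] = change[0] + 0.5  # midpoint between the two runs
        else:
            ambiguous[j] = True
    if ambiguous.mean() > config.max_ambiguous_frac or ambiguous.all():
        return None
    good = ~ambiguous
    idx = np.arange(n_lines)
    samples[ambiguous] = np.interp(idx[ambiguous], idx[good], samples[good])
    x0, y0, _, _ = rect.bounds
    if axis == HORIZONTAL:
        axis_values = x0 + idx.astype(float)
        samples_frame = y0 + samples
    else:
        axis_values = y0 + idx.astype(float)
        samples_frame = x0 + samples
    return InterfaceCurve(
        axis_values=axis_values,
        samples=samples_frame,
        crossing_axis=axis,
        method="clustering",
        ambiguous=ambiguous,
    )


def segment_snake(
    patch: np.ndarray,
    init: InterfaceCurve,
    rect: SearchRectangle,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> InterfaceCurve:
    """Open active contour: maximize gradient along the curve, stay smooth.

    Each sample moves within ±``snake_max_displacement_px`` along the
    crossing normal to maximize interpolated gradient magnitude minus a
    curvature (second-difference) penalty, Jacobi-style, until the largest
    step falls below ``snake_tol_px`` or the iteration cap is reached
    (then flagged).  A flat-gradient patch returns the init, flagged.
    """
    work = patch if init.crossing_axis == HORIZONTAL else patch.T
    x0, y0, _, _ = rect.bounds
    off = y0 if init.crossing_axis == HORIZONTAL else x0
    smoothed = ndimage.gaussian_filter(work.astype(float), 1.0)
    grad = np.abs(np.gradient(smoothed, axis=0))
    pos0 = init.samples - off  # local normal coordinate per line
    cols = np.arange(work.shape[1], dtype=float)
    flags = list(init.flags)
    if grad.max() < 1e-3:
        out = InterfaceCurve(
            axis_values=init.axis_values.copy(),
            samples=init.samples.copy(),
            crossing_axis=init.crossing_axis,
            method="snake",
            ambiguous=init.ambiguous,
            flags=flags + ["flat_gradient"],
        )
        return out
    pos = pos0.copy()
    deltas = np.array([-0.5, -0.25, -0.1, 0.0, 0.1, 0.25, 0.5])
    lam = config.snake_lambda
    band = config.snake_max_displacement_px
    converged = False
    for _ in range(config.snake_max_iter):
        left = np.concatenate([[pos[0]], pos[:-1]])
        right = np.concatenate([pos[1:], [pos[-1]]])
        best = pos.copy()
        best_obj = np.full(pos.shape, -np.inf)
        for d in deltas:
            cand = np.clip(pos + d, pos0 - band, pos0 + band)
            cand = np.clip(cand, 0.0, work.shape[0] - 1.0)
            g = ndimage.map_coordinates(grad, [cand, cols], order=1)
            curv = (left - 2.0 * cand + right) ** 2
            obj = g - lam * curv
            better = obj > best_obj
            best[better] = cand[better]
            best_obj[better] = obj[better]
        step = np.abs(best - pos).max()
        pos = best
        if step < config.snake_tol_px:
            converged = True
            break
    if not converged:
        flags.append("snake_not_converged")
    return InterfaceCurve(
        axis_values=init.axis_values.copy(),
        samples=off + pos,
        crossing_axis=init.crossing_axis,
        method="snake",
        ambiguous=init.ambiguous,
        flags=flags,
    )


def check_hypotheses(
    curve: InterfaceCurve,
    labels: np.ndarray,
    target: str,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict:
    """Evaluate H1-H4 for a candidate interface; returns the record.

    H1 smoothness: max per-step jump ≤ ``h1_max_step_px`` and total
    variation ≤ ``h1_max_tv_frac`` of the crossing extent.  H2 full
    single-valued crossing with no ambiguous samples.  H3 (iris targets):
    a least-squares quadratic fits within ``h3_max_residual_px`` and its
    extremum bulges toward the sclera (brighter) side.  H4: the largest
    4-connected component of each label holds ≥ ``h4_min_component_frac``
    of that label's pixels.
    """
    s = np.asarray(curve.samples, dtype=float)
    rec: dict = {}
    steps = np.abs(np.diff(s))
    extent = len(s)
    rec["H1"] = bool(
        len(s) >= 2
        and np.isfinite(s).all()
        and steps.max(initial=0.0) <= config.h1_max_step_px
        and steps.sum() <= config.h1_max_tv_frac * extent
    )
    rec["H2"] = bool(
        np.isfinite(s).all()
        and (curve.ambiguous is None or not curve.ambiguous.any())
    )
    if target in ("iris_bottom", "iris_lateral"):
        u = np.arange(len(s), dtype=float)
        coeffs = np.polyfit(u, s, 2)
        resid = np.abs(np.polyval(coeffs, u) - s)
        # sclera side: where the brighter cluster lies relative to the curve
        lab = labels if curve.crossing_axis == HORIZONTAL else labels.T
        rows = np.arange(lab.shape[0], dtype=float)[:, None]
        bright = lab == 1
        dark = lab == 0
        if bright.any() and dark.any():
            bright_mean = (rows * bright).sum() / bright.sum()
            dark_mean = (rows * dark).sum() / dark.sum()
            sclera_dir = np.sign(bright_mean - dark_mean)  # +1: below/right
        else:
            sclera_dir = 0.0
        convex_ok = coeffs[0] * sclera_dir < 0 if sclera_dir != 0 else False
        rec["H3"] = bool(convex_ok and resid.max(initial=0.0) <= config.h3_max_residual_px)
    else:
        rec["H3"] = None
    h4 = True
    for value in (0, 1):
        mask = labels == value
        total = mask.sum()
        if total == 0:
            h4 = False
            break
        comp = measure.label(mask, connectivity=1)
        largest = np.bincount(comp.ravel())[1:].max()
        if largest < config.h4_min_component_frac * total:
            h4 = False
            break
    rec["H4"] = bool(h4)
    rec["passed"] = bool(
        rec["H1"] and rec["H2"] and rec["H4"] and (rec["H3"] in (None, True))
    )
    return rec


def segment_with_retry(
    image: np.ndarray,
    rect: SearchRectangle,
    base_seed: int = 0,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> SegmentationOutcome:
    """Full local search with re-seeding and rectangle shrinking.

    Per attempt: enhance the patch, cluster (seed = base_seed + attempt),
    derive the cluster interface, refine with the open snake, require
    clustering/snake concurrence (mean absolute difference ≤
    ``concurrence_tol_px``) and the H1-H4 record to pass.  On failure the
    clustering is re-seeded up to ``reseed_attempts`` times, then the
    rectangle shrinks by ``shrink_factor`` about its anchor, up to
    ``max_shrinks`` times; exhaustion skips the interface for this frame.
    The accepted curve is the snake-refined one.  Deterministic for a
    fixed base seed.
    """
    attempts = 0
    current: SearchRectangle | None = rect
    last_reason = "exhausted"
    last_quality: dict | None = None
    while current is not None:
        patch_raw = current.patch(image)
        if min(patch_raw.shape) < config.min_rect_px or patch_raw.size < 16:
            break
        patch, flat = enhance_contrast(patch_raw, config)
        if flat:
            attempts += 1
            last_reason = "contrast"
            current = current.shrunk(config.shrink_factor, config.min_rect_px)
            continue
        for _ in range(config.reseed_attempts + 1):
            seed = base_seed + attempts
            attempts += 1
            labels, sep = segment_two_cluster(patch, seed, config)
            if sep < config.min_separation_score:
                last_reason = "contrast"
                continue
            init = labels_to_interface(labels, current.crossing_axis, current, config)
            if init is None:
                last_reason = "hypothesis"
                continue
            refined = segment_snake(patch, init, current, config)
            concur = float(np.mean(np.abs(refined.samples - init.samples)))
            if concur > config.concurrence_tol_px:
                last_reason = "hypothesis"
                continue
            quality = check_hypotheses(refined, _majority_filter(labels),
                                       current.target, config)
            quality["separation"] = sep
            quality["concurrence"] = concur
            last_quality = quality
            if quality["passed"]:
                refined.quality = quality
                refined.accepted = True
                return SegmentationOutcome(
                    curve=refined,
                    attempts=attempts,
                    final_rectangle=current,
                    failure_reason="none",
                    last_quality=quality,
                )
            last_reason = "hypothesis"
        current = current.shrunk(config.shrink_factor, config.min_rect_px)
        if current is not None and current.shrink_level > config.max_shrinks:
            current = None
    reason = last_reason if last_reason in ("contrast", "hypothesis") else "exhausted"
    if attempts >= (config.reseed_attempts + 1) * (config.max_shrinks + 1):
        reason = "exhausted"
    return SegmentationOutcome(
        curve=None,
        attempts=attempts,
        final_rectangle=rect,
        failure_reason=reason if reason != "none" else "exhausted",
        last_quality=last_quality,
    )


def segment_eye(
    image: np.ndarray,
    hexagon: EyeHexagon,
    exercise: str,
    gaze: str = "up",
    base_seed: int = 0,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[str, SegmentationOutcome]:
    """Segment every target interface of one eye; keyed by target name."""
    rects = build_rectangles(hexagon, exercise, gaze, image.shape, config)
    return {
        r.target: segment_with_retry(image, r, base_seed=base_seed, config=config)
        for r in rects
    }
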