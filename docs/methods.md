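# Methods

This note documents the models, numerical choices and open design
decisions behind `oculid`, in the spirit of a package reference: what is
computed, under which assumptions, with which knobs, and what the tests
do and do not demonstrate.

## Coordinate and landmark conventions

Images are grayscale in [0, 1], origin top-left, x rightward, y downward,
pixel centers at integer coordinates.  Landmark indices are 1-based as in
the standard 68-point facial annotation: the right-eye hexagon is points
37–42 (temporal corner, two upper-lid points, nasal corner, two lower-lid
points walking back), the left eye 43–48.  Interfaces are single-valued
curves: y(x) per column for lids and iris bottom, x(y) per row for the
lateral iris boundary, with the sub-pixel convention that a region change
between pixels r and r+1 lies at r + 0.5.

## Coarse metrics

* **Eyelid distance (ED)** — mean of the two vertical distances between
  the paired upper/lower lid landmarks (38↔41, 39↔42 right; 44↔48,
  45↔47 left).  Vertical rather than Euclidean distance is used: the
  pairing is a vertical-opening measure and the lid segments are nearly
  horizontal, so the two differ only at second order in the tilt.
* **Eye length (EL)** — |x(corner) − x(corner)|; frames with EL < 4 px
  are under-resolved.  **Eye area** — shoelace area of the hexagon
  (via `shapely`), unavailable when the outline self-intersects.
* Normalization: ED/EL and area/EL² use the *per-frame* EL, so all
  reported channels are invariant under whole-frame translation and
  scaling; this is what makes the metrics usable without controlling the
  patient-to-camera distance.
* ED stays defined for a degenerate (closed-eye) hexagon — a blink must
  read as an ED ≈ 0 dip, not a missing sample.  Only area and the local
  segmentation are unavailable then.
* **Blinks** — a maximal run of frames with ED below 0.5× a rolling
  2 s median baseline, lasting ≤ 0.5 s (longer closures are rests, not
  blinks); single-frame dips count.  Both the threshold and the duration
  cap are config-exposed; the defaults were chosen once from the
  generator's 0.2 s blink profile at 30 FPS.

## Local interface segmentation

Each target interface gets a search rectangle built from the hexagon:
lid rectangles span their landmark segment horizontally, padded
vertically by ±0.15·EL; the iris-bottom rectangle spans the upper
segment's x-range from the upper-lid level down to the lower-lid level;
the lateral box runs from the corner opposite the gaze direction to the
upper/lower lid landmarks on the far side.  All are clipped to the image
and dropped below 4 px a side.

Per attempt: 1st–99th percentile contrast stretch (constant patches are
flagged and fail as `contrast`); a seeded 1-D Lloyd two-means on the
intensities (label 1 = brighter cluster; separation score =
centroid distance / pooled within-cluster σ, minimum 2.0); a 3×3
majority filter; per column (row) the boundary between exactly two label
runs becomes the interface sample, other run structures mark the column
ambiguous (> 20% ambiguous aborts); an open snake then moves each sample
within ±3 px along the crossing normal to maximize interpolated gradient
magnitude minus λ·(second difference)², Jacobi-style, ≤ 50 iterations or
max step < 0.1 px.  λ defaults to 0.05 — on [0, 1]-stretched patches the
step-edge gradient after Gaussian smoothing (σ = 1) is O(0.3), so this λ
tolerates ~2 px curvature before the penalty dominates; it was fixed by
the 2-pixel localization property on the generator, not fitted per
image.

Acceptance requires **H1** (max per-column jump ≤ 2 px, total variation
≤ 0.5× the crossing extent), **H2** (full single-valued crossing, no
ambiguous columns), **H3** for iris arcs (quadratic fit residual ≤ 2 px
and the extremum bulging toward the brighter — scleral — side, the sign
being derived from the label field rather than hard-coded per target),
**H4** (largest 4-connected component holds ≥ 90% of each label), plus
clustering/snake concurrence ≤ 2 px mean absolute difference, matching
the overall 2-pixel accuracy aim.  On failure: two re-seeds, then a 0.8×
shrink about the rectangle's anchor, up to five shrinks, then the frame
is skipped for that interface (`exhausted`).

Anchors: lid and iris-bottom rectangles shrink about their landmark
segment midpoints.  The lateral box shrinks about a point a quarter of
its length from the far-from-corner end: the visible iris boundary lies
toward the opposite-landmark end of the box, and shrinking toward the
corner would walk the search away from the interface.

A note on the separation score: splitting *any* unimodal intensity
sample in two yields centroids ~3 pooled-σ apart (≈ 3.5 for uniform
noise), so the 2.0 gate only rejects near-degenerate patches;
unstructured content is actually eliminated by H1–H4 and retry
exhaustion.  The gate is kept because it is cheap and config-exposed.

## Exam metrics

Curves are evaluated at the ROI-center x.  lid-to-lid and
iris-to-lower-lid distances are reported raw and EL-normalized; small
negative iris-to-lower-lid values (≥ −2 px) are tolerated as sub-pixel
error.  The iris circle is fit algebraically (Kåsa least squares) to the
arc samples, with an explicit collinearity guard (second singular value
of the centered samples < 0.05 px); arcs subtending < 60° are flagged
unreliable.  The pupil center is approximated by the iris-circle center;
no pupil segmentation is attempted.

α = |x(P) − x(anchor corner)| / EL with P the extremal point of the
lateral arc in the gaze direction and the anchor the corner the search
box was drawn from.  α_left − α_right is compared with its baseline (the
median over the first 5 s of frames with both eyes measured), so a
constant inter-ocular offset never flags; deviation > 0.05 (config)
raises the misalignment flag, reported alongside the raw series.

Grades: the time scale maps droop onset — the first time the filtered
lid opening falls below 90% of its initial value (config) — to 0–3
(none within 45 s / 11–45 s / ≤ 10 s / ≤ 1 s); a series shorter than
45 s without onset cannot certify grade 0 and returns unavailable.  The
anatomic scale compares the upper lid to the fitted iris: above the iris
top / above the pupil band / within ±¼ diameter of the center ("at
pupil") / below.  The onset fraction and band width quantify scale
wordings that are qualitative in the clinical instrument; both are
config-exposed.

## Exercise window and frame rejection

Gaze per frame comes from two-clustering the hexagon interior and
locating the sclera-like (bright) centroid relative to the iris-like
(dark) one: sclera below → up-gaze, sclera on one side → lateral gaze
(threshold 0.06·EL).  Both eyes must agree; votes are smoothed over 1 s,
and neutral stretches ≤ 5 s without counter-votes (blinks, rest
closures) do not split a window.  The longest run of the expected label
is the exercise window; runs < 10 s give none, durations outside
[40, 80] s are flagged atypical.

Rejection reasons, exclusive in priority order: **motion** (median
landmark displacement between consecutive frames > 0.1·EL), **lighting**
(a required rectangle's last hypothesis record failed H4 — non-connex
clusters, the signature of reflections), **landmark instability**
(eye-hexagon centroid jump > 0.2·EL while the median face landmark moves
< 0.05·EL), **blink** (inside a detected event ± one frame).  The three
fractions quantify qualitative checks and are config-exposed.  In
Exercise 2 only the lateral-iris rectangle is required — in lateral gaze
the iris abuts the lid interfaces and the lid boxes become three-class,
so lid curves there are best-effort extras.

## Series, filter, trend

Valid in-window samples form each channel; holes ≤ 1 s are linearly
interpolated on the native frame grid, longer holes are recorded as gaps
and never filled — not by interpolation and not by the filter.  Each
contiguous segment ≥ 4 s is resampled uniformly at its mean rate,
extended by its mirror image (even extension, removing the periodicity
mismatch a plain DFT would see at the segment ends), sharply low-passed
at 0.5 Hz, inverted and truncated.  Consequences, all tested: constants
and linear ramps pass within 1% (the mirrored ramp is a triangle wave
whose harmonics decay as 1/n²), a 5 Hz sinusoid is attenuated ≥ 20×
(measured ≈ 75× away from the segment ends), the mean is preserved to
0.1%, and the filter is idempotent to 1%.  Segments < 4 s pass through
unfiltered, flagged.  The trend is ordinary least squares on time
normalized to [0, 1] over the non-gap support (≥ 10 samples spanning
≥ 50% of the window), so the slope reads directly as the total change
over the exercise; the relative lid-opening decay is −slope/intercept.

## Synthetic generator

Each eye is a palpebral aperture between two parabolic lid curves
through the corners, filled with sclera, plus an iris disk clipped to
the aperture, on flat skin; then a linear illumination ramp and
per-frame seeded Gaussian noise.  Defaults model the telehealth study
conditions: 450×800 frames at 30 FPS, 61 s exercises, EL = 60 px with a
30 px aperture (apertures 10–45 px are exercised in tests via a
geometry-scaling factory), intensities skin 0.55 / sclera 0.90 /
iris 0.15 with a 0.2 contrast margin, noise σ = 0.02.  Droop is a linear
upper-lid descent in fractions of the initial aperture per second
(decay over 60 s = 60·rate); blinks close and reopen the upper lid over
0.2 s; sustained closures, per-eye iris drift (misalignment), gaze
direction and Gaussian whole-geometry head jitter are programmable.
Ground truth per frame: exact lid/iris curves, landmark hexagons, ED,
EL, area and α.  The companion landmark fixture provider returns these
hexagons inside a plausible 68-point face scaffold (clamped to the
frame, as with a close-up crop), with optional bias/noise to emulate
landmark-model error.

What passing tests show: the pipeline recovers interfaces to ≤ 2 px and
programmed decays to ≤ 0.03 under realistic geometry, contrast, noise,
lighting gradients, blinks and translation.  What they do not show:
robustness to eyelashes, specular highlights, compression artifacts,
skin/iris appearance diversity or rotational head motion — real-video
success rates will be lower, and the rejection machinery exists
precisely to skip such frames rather than measure them badly.

## Problem sizes and runtime

The acceptance script samples full-length 61 s, 30 FPS sequences at one
frame per 0.2 s (305 frames per sequence) for the droop-recovery runs,
uses 100 frames across five geometry/noise conditions for the
localization study, 50 patches for the oracle comparison, and full
1830-frame landmark tracks for blink detection; it completes in about a
minute on one CPU.  These sizes are the package's chosen validation
scale: they are large enough that the measured rates are stable to a few
percent across seeds.

## Known limitations

Lid curves in lateral gaze are frequently unavailable by design; iris
diameter requires a primary-gaze arc subtending ≥ 60°; the anatomic
grade is unavailable whenever the iris fit is unreliable (typically in
up-gaze, where only a short bottom arc is visible); video-container
decoding depends on the imageio backend present, with frame directories
as the fully supported interchange; and the external landmark adapter
requires its backend at runtime — the package neither bundles nor trains
a landmark model.
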