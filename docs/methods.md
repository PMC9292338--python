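# Methods

This note documents the models, parameter choices and numerical details of
the `uristrip` pipeline, and what its synthetic benchmarks do and do not
show about real photographs.

## Layout model

A `StripLayout` is a declarative document (JSON/YAML, validated against a
published JSON Schema) describing the strip and its reference card: the ten
analyte parameters in physical order from the dipped end, each with an
ordered list of graded levels (label, semantic value + unit, swatch sRGB
color) and a manufacturer read time in {30, 40, 45, 60, 120} s; the
canonical card frame with one rectangle per (parameter, level) swatch; and
the strip's canonical geometry (pad side 40 px, pitch 56 px in the shipped
layout). Conventions: 0-based pixel coordinates, rectangles as
(x, y, w, h), y down.

The shipped default is Multistix-like but *schematic*: the paper card's
true coordinates and level values are manufacturer data, so each level's
color is generated from a per-analyte hue ramp (monotone in hue, adjacent
levels ≥ 15° apart) rather than measured chemistry. The physical pad order
from the dipped end is an assumption of the default file. Deployments must
replace colors, values and coordinates with manufacturer measurements; the
code reads everything from the layout.

## Card detection and rectification

Both the canonical card template and the scene are converted to grayscale
and contrast-stretched (2nd–98th percentile to full range) — overexposed
photos otherwise clip the card's near-white backing and flatten the binary
descriptors. ORB features (default budget 600 keypoints; chosen so that a
cluttered background cannot starve the card of keypoints) are matched
exhaustively with the Hamming metric, no ratio test, cross-checking off.
Matches are sorted by ascending distance and the best 50 kept; a projective
homography is estimated by RANSAC (reprojection threshold 5 px, 1000
trials, fixed seed for reproducible reports).

A coarse-to-fine refinement follows: the scene is warped into the canonical
frame with the initial homography, features re-matched under a 10 px
spatial gate, and a corrective homography (RANSAC, 2 px threshold)
composed onto the first. The gate is under half the swatch pitch, so the
correction cannot re-lock onto a grid-shifted position; it reduces the mean
corner error from a few pixels to well under one.

Detection *succeeds* when ≥ 10 matches are kept, ≥ 8 are inliers, the
recovered quad is convex and covers ≥ 1 % of the scene; otherwise a
`DetectionFailure` with match diagnostics is raised. The canonical card
template is rendered programmatically from the layout; besides the swatch
grid it carries a frame, corner fiducials and a fixed-seed speckle pattern
in the label band, gutters and margins. The speckle is part of the template
design, not decoration: a bare swatch grid is self-similar under shifts by
one row/column pitch, and binary descriptors will happily lock onto the
shifted grid. Deployments using a real manufacturer card get such texture
for free from the printed labels.

Strip detection by the same template matching is possible but not the
supported path — a nearly texture-free strip gives few distinctive
features — so the pipeline takes a user-supplied strip region of interest
(or, with a warning, searches the full scene).

## Test-field localization

The strip crop is preprocessed under a grid of settings: blur σ ∈
{0, 1, 5/3, 7/3} px × binarizers {global Otsu, local-mean adaptive
(block 35), Canny (σ = 1, thresholds 50/255 and 150/255) with hole
filling, Otsu on the saturation channel, Otsu per RGB channel}. Threshold
masks are taken in both polarities. The channel-wise settings matter:
yellow pads on a white strip can be luminance-isoluminant with the backing
and invisible to any grayscale setting, but always stand out in saturation
or in the blue channel. For each connected region, the boundary contour is
reduced with polygon approximation at escalating tolerance (2/4/6 % of the
perimeter — noise nibs on an edge survive the smallest tolerance); a
candidate must be a convex quadrilateral, aspect within 1 ± 0.06 (opposite
side lengths averaged so single-pixel contour jitter on one edge cannot
decide), and side ≥ 0.2 × the crop's transverse extent (min of height and
width, which keeps the rule meaningful for portrait crops). The minimum-
size rule is read as a length, not an area: a pad spans most of the strip's
transverse extent, and "20 % of the height" as an area would be
dimensionally inconsistent. Candidates from all settings are pooled;
duplicates deliberately weight the clustering.

Candidate centers are clustered with k-means (k-means++ init, 10 restarts,
caller seed). k ranges over 1..(expected pads + 2) and is chosen by the
elbow rule, implemented as the maximum second difference of **log** WCSS
(ties to smaller k). The log scale is essential: for spread-out cluster
arrangements raw WCSS decays convexly in k and its plain second difference
peaks at k = 2 regardless of the true count, while log-WCSS drops sharply
exactly when k reaches the number of tight blobs.

Grid completion projects the centers on their principal axis (deterministic
sign: dominant component positive). Near-duplicates (< 0.5 × median gap)
are merged. The pitch is the median consecutive spacing, made robust to
skipped pads by dividing each gap by its rounded multiple of the smallest
gap. Gaps > 1.5 × pitch are filled with round(gap/pitch) − 1 equally
spaced points; if the grid is still short, points are extrapolated by one
pitch beyond the ends, alternating starting at the dipped end, skipping an
end whose next point would leave the image. Needing more than half the
expected count by extrapolation is a failure, not a guess. Completed
centers are snapped onto the fitted midline (pads are collinear; a
transverse offset on one detected center is clutter). Each center receives
a sampling patch of half the median candidate side, and patches map to
parameters in layout order along the axis — the dipped end is taken to be
the low-coordinate end of the crop, which geometry alone cannot verify.

## Colorimetry

Patches are converted to HSV; each channel is histogrammed (360 one-degree
hue bins; 256 bins for s and v) and the peak bin center taken, ties to the
lowest bin. An achromatic peak (s < 0.05) reports hue 0. The three
similarity measures are defined in the README; all use the circular hue
difference (the hue channel is an angle; without wrap-around, two reds at
5° and 355° would count as maximally different). In the matching factor the
channels are unit-normalized (H_max = S_max = V_max = 1, ΔH/360 before
weighting): the weights α = 0.6429 ≈ 3.6 β sum to ≈ 1 with 2β, which only
yields a score bounded in [0, 1] if each channel term is ≤ 1. The hue
method gets an optional achromatic guard (default on, configurable): when
either color has s < 0.05 its hue is numerically meaningless, and the
score falls back to the matching factor's saturation/value terms. This is
an extension beyond the plain hue comparison, needed for the white
negative nitrite pad.

The matched level is the argmax of similarity over the parameter's
reference levels, ties toward the lower concentration (a deliberate
clinical bias: under ambiguity report the less pathological level).

## Classification and timing

pH is positive strictly above 7.0 (7.0 itself negative); specific gravity
is negative on the inclusive band [1.005, 1.025] g/ml; urobilinogen is
negative strictly below 1 mg/dl; every other analyte is negative exactly
when the matched level is the layout's lowest (below detection limit).
Each parameter carries its read time; `analyze_session` reads each
parameter from the image captured at its read time, and single-image mode
is allowed with a logged warning since pad colors keep developing.

## Synthetic scenes

`render_scene` paints the canonical card and a strip with planted levels,
warps each by a random homography (each corner displaced uniformly within
warp_magnitude × the object's *smaller* side — perspective displacement is
roughly isotropic, and scaling by the strip's long side would shear its
pads far out of square), composites onto a procedural background (solid /
smooth texture / texture with random shapes; no downloaded images), then
applies brightness shift, Gaussian blur and pixel noise in that fixed
order (reorderings change peak colors). Compositing is nearest-neighbor so
an undegraded scene reproduces planted colors exactly. Ground truth
records homographies, scene-space pad quads, planted levels/colors and the
seed; per-scene seeds derive from one master seed and everything is
byte-deterministic.

Default conditions (seed aside): warp 0.08, blur σ 0.5 px, noise σ 0.01,
texture background. The benchmarks use warp ≤ 0.15 / blur ≤ 1.5 /
brightness ± 0.2 for detection stress, and a "clean capture" setting
(warp 0.05, blur 0.5, noise 0.01) for field localization and end-to-end
recovery — a careful hand-held photo. Problem sizes: 100 scenes
(detection), 50 strips (field grid), 60 scenes spanning every level of
every parameter (end-to-end).

What the generator does **not** emulate: shadows, specular highlights,
color casts / white-balance error (the pipeline performs no color
constancy), lens distortion, motion blur, camera tone curves, wear or
contamination of real pads, and chemical color development over time.
Passing synthetic benchmarks therefore demonstrates the geometry and
colorimetric machinery, not field robustness; the numbers are stand-ins
measured under controlled conditions, not estimates of accuracy on real
photographs.

## Known limitations

- A strip foreshortened by more than ~6 % makes its pads fail the
  1 ± 0.06 aspect filter wholesale; the filter band is part of the method
  definition, so such crops fail loudly (GridCompletionFailure) rather
  than degrade silently.
- The dipped-end orientation of the strip cannot be inferred from
  geometry; a strip presented backwards is mis-assigned.
- Levels of one parameter that differ only in saturation/value are
  indistinguishable to the hue method; the shipped schematic layout spaces
  levels in hue, real cards may not.
- The evaluation harness reports both macro-averaged (per parameter) and
  pooled F1, since "average F1" is ambiguous between the two.
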