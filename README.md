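# uristrip

Automated colorimetric reading of urine test strips from smartphone
photographs.

Routine urinalysis with 10-pad dipsticks (glucose, bilirubin, ketone,
specific gravity, blood, pH, protein, urobilinogen, nitrite, leukocytes) is
normally read by eye against a printed reference card — slow,
operator-dependent and error-prone. `uristrip` automates the comparison on
an ordinary photograph that shows the dipped strip next to its reference
card, with no extra hardware:

1. **Card rectification.** ORB keypoints (oriented FAST + rotated BRIEF
   binary descriptors) are extracted from the photo and from the canonical
   card template, matched exhaustively under the Hamming metric; the best
   matches feed a RANSAC homography *H* that warps the card into its
   canonical frame, where every reference swatch sits at known pixel
   coordinates.
2. **Test-field localization.** The strip crop is preprocessed under a grid
   of blur/threshold/edge settings; contours that reduce to convex
   quadrilaterals with aspect ratio 1 ± 0.06 and side ≥ 0.2 × the crop's
   transverse extent are pooled as pad candidates. Candidate centers are
   clustered with k-means (cluster count chosen by the elbow rule on the
   within-cluster sum of squares) and the grid is completed: gaps wider
   than 1.5 × the median spacing are filled, missing end pads extrapolated.
3. **Colorimetric matching.** Each pad and swatch is reduced to its
   dominant HSV color by per-channel histogram peak, and compared with
   three similarity measures (ΔH is the circular hue difference; channels
   unit-normalized):

   - hue: `S_hue = 1 − ΔH / H_max`, `H_max = 360°`
   - matching factor:
     `MF = 1 − (α·ΔH + β·ΔS + β·ΔV) / (H_max + S_max + V_max)` with
     `α = 0.6429`, `β = 0.1786`
   - Euclidean distance between cylinder coordinates
     `(s·cos h, s·sin h, v)`:
     `S_eucl = 1 − d / √((2·S_max)² + V_max²)`

   The reference level with the highest similarity is the result; levels
   are then classified negative/positive (pH positive above 7.0, specific
   gravity negative within 1.005–1.025 g/ml, urobilinogen negative below
   1 mg/dl, all other analytes negative at the below-detection-limit
   level).

A seeded synthetic scene generator replaces study photographs: it renders
the card and a strip with planted levels under perspective warp,
brightness shift, blur and noise, and records exact ground truth, so the
whole pipeline is testable offline. The shipped layout's swatch colors and
level values are schematic placeholders — a clinical deployment must
substitute the strip manufacturer's values (see `uristrip schema` and
`src/uristrip/data/default_layout.json`).

## Worked example

Render a synthetic scene and analyze it (the manifest stores the strip's
bounding box; on real photos you supply the strip region yourself):

```sh
uristrip simulate -n 1 --seed 42 --out demo
uristrip analyze demo/scene_00000.png --strip-roi 81,433,576,78 --method hue
```

Abridged output:

```json
{
  "card_detection": {"n_matches_kept": 50, "n_inliers": 50},
  "results": {
    "hue": [
      {"parameter": "glucose", "level": "negative", "value": null,
       "scores": {"hue": 1.0}, "classification": "negative", "read_time_s": 30},
      {"parameter": "bilirubin", "level": "large", "value": 3.0,
       "scores": {"hue": 1.0}, "classification": "positive", "read_time_s": 30},
      {"parameter": "ketone", "level": "moderate", "value": 40.0,
       "scores": {"hue": 1.0}, "classification": "positive", "read_time_s": 40}
    ]
  },
  "warnings": ["single-image mode: all parameters read from one photo; ..."]
}
```

All 50 kept feature matches were homography inliers; each pad's matched
level carries its similarity score (1.0 = exact color match), semantic
value and the negative/positive call. The scene planted `bilirubin=large`
and `ketone=moderate`, both recovered. `uristrip evaluate --pred … --manifest …`
scores a batch of such reports against the generator's ground truth as
per-parameter confusion matrices with F1.

Because pads develop on a schedule (30–120 s after dipping), `analyze`
accepts one image per read time (`--read-times 30,40,45,60,120`); with a
single image it reads everything from that photo and warns.

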