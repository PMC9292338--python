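"""Deterministic synthetic scene generation with full ground truth.

Real study photographs are replaced by rendered scenes: the canonical
reference card and a strip carrying planted level colors are painted from
the layout, warped by seeded random homographies onto a procedurally
generated background, and degraded (brightness shift, then Gaussian blur,
then pixel noise — the order matters for peak colors and is fixed). The
ground-truth manifest records the exact homographies, the scene-space field
quadrilaterals, the planted levels and their colors, and the seed, so every
pipeline stage can be scored without any real photograph.

Rendering is deliberately non-photorealistic: no shadows, speculars or
camera response curves. Compositing uses nearest-neighbor sampling so that
an undegraded scene reproduces the planted colors exactly.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.filters import gaussian
from skimage.transform import ProjectiveTransform, warp

from .colorimetry import HsvPeak
from .layout import StripLayout

#: Scene raster size (width, height); the card occupies the upper lane,
#: the strip the lower one, so the two never overlap under any allowed warp.
SCENE_W, SCENE_H = 680, 560
_CARD_LANE_H = 430

BACKGROUNDS = ("solid", "texture", "photo-like")

# fixed seed of the card template's fiducial speckle; part of the canonical
# template definition, identical for every render
_TEMPLATE_SPECKLE_SEED = 12345


@dataclass(frozen=True)
class SceneConfig:
    """Degradation and planting knobs of one rendered scene."""
    seed: int
    planted_levels: dict[str, str] = field(default_factory=dict)
    warp_magnitude: float = 0.08       # corner displacement, fraction of size
    blur_sigma_px: float = 0.5
    brightness_delta: float = 0.0      # additive, on the [0, 1] scale
    noise_sigma: float = 0.01          # Gaussian pixel noise std, [0, 1] scale
    background: str = "texture"
    degrade_fields: tuple[str, ...] = ()

    def validate(self, layout: StripLayout) -> None:
        if not 0 <= self.warp_magnitude <= 0.3:
            raise ValueError("warp_magnitude must be in [0, 0.3]")
        if not -0.3 <= self.brightness_delta <= 0.3:
            raise ValueError("brightness_delta must be in [-0.3, 0.3]")
        if not 0 <= self.noise_sigma <= 0.1:
            raise ValueError("noise_sigma must be in [0, 0.1]")
        if self.blur_sigma_px < 0:
            raise ValueError("blur_sigma_px must be >= 0")
        if self.background not in BACKGROUNDS:
            raise ValueError(f"background must be one of {BACKGROUNDS}")
        for name, label in self.planted_levels.items():
            layout.parameter(name).level(label)  # KeyError if absent
        for name in self.degrade_fields:
            layout.parameter(name)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["degrade_fields"] = list(self.degrade_fields)
        return d


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score the pipeline on a rendered scene."""
    card_homography: np.ndarray     # (3, 3), canonical card -> scene
    strip_homography: np.ndarray    # (3, 3), canonical strip -> scene
    card_quad: np.ndarray           # (4, 2) scene xy, TL TR BR BL
    strip_quad: np.ndarray
    field_rects_scene: dict[str, np.ndarray]   # parameter -> (4, 2) quad
    planted_levels: dict[str, str]
    planted_colors: dict[str, HsvPeak]
    seed: int

    def strip_bbox(self, margin: int = 6) -> tuple[int, int, int, int]:
        """Axis-aligned scene bounding box of the strip, padded by ``margin``."""
        q = self.strip_quad
        x0 = max(int(np.floor(q[:, 0].min())) - margin, 0)
        y0 = max(int(np.floor(q[:, 1].min())) - margin, 0)
        x1 = min(int(np.ceil(q[:, 0].max())) + margin, SCENE_W)
        y1 = min(int(np.ceil(q[:, 1].max())) + margin, SCENE_H)
        return (x0, y0, x1 - x0, y1 - y0)

    def to_dict(self) -> dict:
        return {
            "card_homography": self.card_homography.tolist(),
            "strip_homography": self.strip_homography.tolist(),
            "card_quad": self.card_quad.tolist(),
            "strip_quad": self.strip_quad.tolist(),
            "field_rects_scene": {k: v.tolist()
                                  for k, v in self.field_rects_scene.items()},
            "planted_levels": dict(self.planted_levels),
            "planted_colors": {k: [p.h, p.s, p.v]
                               for k, p in self.planted_colors.items()},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            card_homography=np.asarray(d["card_homography"]),
            strip_homography=np.asarray(d["strip_homography"]),
            card_quad=np.asarray(d["card_quad"]),
            strip_quad=np.asarray(d["strip_quad"]),
            field_rects_scene={k: np.asarray(v)
                               for k, v in d["field_rects_scene"].items()},
            planted_levels=dict(d["planted_levels"]),
            planted_colors={k: HsvPeak(*v)
                            for k, v in d["planted_colors"].items()},
            seed=int(d["seed"]),
        )


# ---------------------------------------------------------------------------
# canonical templates
# ---------------------------------------------------------------------------

def render_card_template(layout: StripLayout) -> np.ndarray:
    """Paint the canonical reference card: swatch grid, frame, corner
    fiducials and a deterministic speckle band (texture for the feature
    detector). Identical output on every call for a given layout."""
    cw, ch = layout.card_size
    img = np.full((ch, cw, 3), 245, dtype=np.uint8)
    img[:2], img[-2:], img[:, :2], img[:, -2:] = 20, 20, 20, 20  # frame
    for (x0, y0), flip in (((5, 5), False), ((cw - 15, 5), True),
                           ((5, ch - 15), True), ((cw - 15, ch - 15), False)):
        img[y0:y0 + 10, x0:x0 + 10] = 30
        if flip:
            img[y0 + 3:y0 + 7, x0 + 3:x0 + 7] = 220
    rng = np.random.default_rng(_TEMPLATE_SPECKLE_SEED)
    for _ in range(180):  # speckle in the label band (left edge)
        x = rng.integers(4, 36)
        y = rng.integers(18, ch - 6)
        w = int(rng.integers(2, 6))
        h = int(rng.integers(2, 5))
        shade = int(rng.integers(20, 160))
        img[y:y + h, x:x + w] = shade
    for _ in range(80):  # speckle in the top band
        x = rng.integers(18, cw - 18)
        y = rng.integers(3, 14)
        w = int(rng.integers(2, 7))
        h = int(rng.integers(2, 5))
        shade = int(rng.integers(20, 160))
        img[y:y + h, x:x + w] = shade
    # dots over the whole card; those under a swatch are painted over below,
    # the survivors in the gutters make every grid neighborhood unique and
    # break the row/column self-similarity that would otherwise let feature
    # matches lock onto a swatch-pitch-shifted homography
    for _ in range(700):
        x = rng.integers(3, cw - 6)
        y = rng.integers(3, ch - 6)
        d = int(rng.integers(2, 6))
        shade = int(rng.integers(0, 140))
        img[y:y + d, x:x + d] = shade
    for p in layout.parameters:
        for lv in p.levels:
            x, y, w, h = layout.card_rect(p.name, lv.label)
            img[y:y + h, x:x + w] = lv.color_rgb
    return img


def strip_field_rects(layout: StripLayout) -> list[tuple[int, int, int, int]]:
    """Canonical-strip rectangles of the test pads, dipped end first."""
    sw, sh = layout.strip_size
    n = layout.expected_count
    side, pitch = layout.field_side, layout.field_pitch
    x0 = (sw - ((n - 1) * pitch + side)) // 2
    y0 = (sh - side) // 2
    return [(x0 + i * pitch, y0, side, side) for i in range(n)]


_STRIP_BG = (235, 235, 232)


def render_strip_template(layout: StripLayout, planted: dict[str, str],
                          degrade: tuple[str, ...] = ()) -> np.ndarray:
    """Paint the canonical strip with each pad in its planted level color.

    Pads listed in ``degrade`` are blended 85 percent toward the strip
    background, simulating a washed-out, low-contrast pad that the edge
    detector will miss.
    """
    sw, sh = layout.strip_size
    img = np.full((sh, sw, 3), _STRIP_BG, dtype=np.uint8)
    for p, (x, y, w, h) in zip(layout.parameters, strip_field_rects(layout)):
        color = np.array(p.level(planted[p.name]).color_rgb, dtype=float)
        if p.name in degrade:
            color = 0.85 * np.array(_STRIP_BG) + 0.15 * color
        img[y:y + h, x:x + w] = color.round().astype(np.uint8)
    return img


# ---------------------------------------------------------------------------
# scene composition
# ---------------------------------------------------------------------------

def _background(rng: np.random.Generator, kind: str) -> np.ndarray:
    base = rng.uniform(0.25, 0.85, size=3)
    img = np.broadcast_to(base, (SCENE_H, SCENE_W, 3)).copy()
    if kind == "solid":
        return img
    coarse = rng.normal(0, 1, size=(SCENE_H // 40, SCENE_W // 40))
    tex = ndimage.zoom(coarse, 40, order=3)[:SCENE_H, :SCENE_W]
    img = np.clip(img + 0.08 * tex[..., None], 0, 1)
    if kind == "photo-like":
        yy, xx = np.mgrid[0:SCENE_H, 0:SCENE_W]
        for _ in range(10):
            color = rng.uniform(0, 1, size=3)
            cx, cy = rng.uniform(0, SCENE_W), rng.uniform(0, SCENE_H)
            rx, ry = rng.uniform(15, 90, size=2)
            if rng.random() < 0.5:
                m = (np.abs(xx - cx) < rx) & (np.abs(yy - cy) < ry)
            else:
                m = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 < 1
            img[m] = 0.6 * img[m] + 0.4 * color
    return img


def _random_quad(rng: np.random.Generator, ow: int, oh: int,
                 x_lane: tuple[float, float], y_lane: tuple[float, float],
                 magnitude: float) -> np.ndarray:
    """Base rectangle placed in a lane, each corner displaced independently
    and uniformly within magnitude x object size.

    Object size is the smaller side: perspective displacement is roughly
    isotropic, and tying it to the long side of the elongated strip would
    shear its pads far out of square."""
    mx = my = magnitude * min(ow, oh)
    x0 = rng.uniform(x_lane[0] + mx, x_lane[1] - ow - mx)
    y0 = rng.uniform(y_lane[0] + my, y_lane[1] - oh - my)
    base = np.array([[x0, y0], [x0 + ow, y0],
                     [x0 + ow, y0 + oh], [x0, y0 + oh]])
    disp = np.column_stack([rng.uniform(-mx, mx, 4), rng.uniform(-my, my, 4)])
    return base + disp


def _estimate_homography(canonical: np.ndarray, quad: np.ndarray
                         ) -> ProjectiveTransform:
    if hasattr(ProjectiveTransform, "from_estimate"):
        tform = ProjectiveTransform.from_estimate(canonical, quad)
        if not tform:
            raise RuntimeError("degenerate homography in scene construction")
        return tform
    tform = ProjectiveTransform()
    if not tform.estimate(canonical, quad):
        raise RuntimeError("degenerate homography in scene construction")
    return tform


def _composite(scene: np.ndarray, template: np.ndarray,
               tform: ProjectiveTransform) -> None:
    th, tw = template.shape[:2]
    warped = warp(template.astype(np.float64) / 255.0, tform.inverse,
                  output_shape=(SCENE_H, SCENE_W), order=0, cval=0.0)
    mask = warp(np.ones((th, tw)), tform.inverse,
                output_shape=(SCENE_H, SCENE_W), order=0, cval=0.0) > 0.5
    scene[mask] = warped[mask]


def render_scene(layout: StripLayout, config: SceneConfig
                 ) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene and its ground truth. Byte-deterministic in
    (layout, config)."""
    config.validate(layout)
    rng = np.random.default_rng(config.seed)

    planted = dict(config.planted_levels)
    for p in layout.parameters:  # fill unplanted parameters uniformly
        if p.name not in planted:
            planted[p.name] = str(rng.choice([lv.label for lv in p.levels]))

    scene = _background(rng, config.background)

    card = render_card_template(layout)
    strip = render_strip_template(layout, planted,
                                  degrade=tuple(config.degrade_fields))
    cw, ch = layout.card_size
    sw, sh = layout.strip_size
    card_canon = np.array([[0, 0], [cw, 0], [cw, ch], [0, ch]], dtype=float)
    strip_canon = np.array([[0, 0], [sw, 0], [sw, sh], [0, sh]], dtype=float)

    card_quad = _random_quad(rng, cw, ch, (0, SCENE_W), (0, _CARD_LANE_H),
                             config.warp_magnitude)
    strip_quad = _random_quad(rng, sw, sh, (0, SCENE_W),
                              (_CARD_LANE_H + 4, SCENE_H),
                              config.warp_magnitude)
    card_tf = _estimate_homography(card_canon, card_quad)
    strip_tf = _estimate_homography(strip_canon, strip_quad)
    _composite(scene, card, card_tf)
    _composite(scene, strip, strip_tf)

    field_quads: dict[str, np.ndarray] = {}
    for p, (x, y, w, h) in zip(layout.parameters, strip_field_rects(layout)):
        rect = np.array([[x, y], [x + w, y], [x + w, y + h], [x, y + h]],
                        dtype=float)
        field_quads[p.name] = strip_tf(rect)

    # degradations, in fixed order: brightness -> blur -> noise
    if config.brightness_delta:
        scene = scene + config.brightness_delta
    if config.blur_sigma_px > 0:
        scene = gaussian(scene, sigma=config.blur_sigma_px, channel_axis=-1)
    if config.noise_sigma > 0:
        scene = scene + rng.normal(0, config.noise_sigma, size=scene.shape)
    scene_u8 = (np.clip(scene, 0, 1) * 255).round().astype(np.uint8)

    colors = {}
    for p in layout.parameters:
        r, g, b = layout.parameter(p.name).level(planted[p.name]).color_rgb
        hh, ss, vv = colorsys.rgb_to_hsv(r / 255, g / 255, b / 255)
        colors[p.name] = HsvPeak(h=hh * 360.0, s=ss, v=vv)

    gt = GroundTruth(
        card_homography=card_tf.params.copy(),
        strip_homography=strip_tf.params.copy(),
        card_quad=card_quad, strip_quad=strip_quad,
        field_rects_scene=field_quads,
        planted_levels=planted, planted_colors=colors, seed=config.seed)
    return scene_u8, gt


def generate_dataset(layout: StripLayout, n: int, base_config: SceneConfig,
                     seed: int, out_dir: str | Path | None = None,
                     ) -> list[dict]:
    """Render ``n`` scenes with per-scene seeds derived from ``seed``.

    Unplanted parameters get levels drawn uniformly per scene. Returns the
    manifest (one record per scene); when ``out_dir`` is given, images are
    written as PNG next to a ``manifest.jsonl``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n)
    records: list[dict] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(scene_seeds):
        cfg_args = base_config.to_dict()
        cfg_args["seed"] = int(s)
        cfg_args["degrade_fields"] = tuple(cfg_args["degrade_fields"])
        cfg = SceneConfig(**cfg_args)
        img, gt = render_scene(layout, cfg)
        name = f"scene_{i:05d}.png"
        rec = {"image": name, "seed": int(s), "config": cfg.to_dict(),
               "ground_truth": gt.to_dict()}
        records.append(rec)
        if out is not None:
            iio.imwrite(out / name, img)
    if out is not None:
        with open(out / "manifest.jsonl", "w") as fh:
            for rec in records:
                fh.write(json.dumps(rec) + "\n")
    return records


def load_manifest(path: str | Path) -> list[dict]:
    """Read a JSON-lines manifest written by :func:`generate_dataset`."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    return records
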