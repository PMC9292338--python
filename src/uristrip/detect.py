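"""Reference-card localization by binary-descriptor feature matching.

The canonical card template and the scene photograph are converted to
grayscale; oriented-FAST keypoints with rotated-BRIEF (ORB) binary
descriptors are extracted from both, matched exhaustively under the Hamming
metric, the best matches kept, and a projective homography estimated
robustly (RANSAC) from the kept correspondences. The scene is then warped
into the template's canonical frame, where swatch coordinates are constant.

The same operation can be pointed at a strip template, but plain feature
matching on the nearly texture-free strip is unreliable; the supported strip
localization path is the edge-based field finder in :mod:`uristrip.fields`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform, warp

from .errors import DetectionFailure


@dataclass(frozen=True)
class MatchingConfig:
    """Tunables of the detection stage.

    max_features: ORB keypoint budget per image.
    matches_kept: matches retained after sorting by ascending Hamming
        distance ("only best matches are kept"); caps the cost of the
        robust fit.
    ransac_threshold_px: reprojection residual below which a
        correspondence counts as an inlier.
    min_matches / min_inliers: success criteria; below either the
        detection is reported as failed rather than returning a garbage
        homography.
    min_area_frac: detected quad must cover at least this fraction of the
        scene.
    seed: RANSAC sampling seed; fixed so reports are reproducible.
    """
    max_features: int = 600
    matches_kept: int = 50
    ransac_threshold_px: float = 5.0
    min_matches: int = 10
    min_inliers: int = 8
    min_area_frac: float = 0.01
    seed: int = 0
    refine: bool = True
    refine_radius_px: float = 10.0
    refine_threshold_px: float = 2.0


@dataclass(frozen=True)
class FeatureSet:
    """ORB keypoints as (x, y, scale, orientation) rows + binary descriptors."""
    keypoints: np.ndarray    # (n, 4) float
    descriptors: np.ndarray  # (n, 256) bool

    def __len__(self) -> int:
        return len(self.keypoints)


@dataclass(frozen=True)
class DetectedObject:
    """Rectification result.

    ``corners`` are the template's four canonical corners located in the
    scene, ordered top-left, top-right, bottom-right, bottom-left of the
    canonical frame. ``homography`` maps scene (x, y) to canonical (x, y).
    """
    corners: np.ndarray      # (4, 2) scene xy
    homography: np.ndarray   # (3, 3), scene -> canonical
    n_matches_kept: int
    n_inliers: int


def _to_gray(image: np.ndarray) -> np.ndarray:
    """Grayscale + percentile contrast stretch.

    Overexposed photos clip the card's near-white backing and flatten the
    binary descriptors; stretching the 2nd-98th percentile to full range
    restores local contrast and is a no-op on well-exposed images.
    """
    image = np.asarray(image)
    if image.ndim == 3:
        image = rgb2gray(image)
    elif image.dtype == np.uint8:
        image = image.astype(np.float64) / 255.0
    lo, hi = np.percentile(image, (2, 98))
    if hi - lo > 1e-6:
        image = np.clip((image - lo) / (hi - lo), 0.0, 1.0)
    return image


def extract_features(image: np.ndarray, max_features: int = 400) -> FeatureSet:
    """ORB keypoints and binary descriptors of a grayscale image.

    Returns an empty FeatureSet (not an error) on images without corners,
    e.g. a uniform patch of wall.
    """
    if max_features < 1:
        raise ValueError("max_features must be >= 1")
    gray = _to_gray(image)
    orb = ORB(n_keypoints=max_features, fast_threshold=0.05)
    try:
        orb.detect_and_extract(gray)
    except RuntimeError:  # raised by skimage when no keypoints survive
        empty = np.empty((0, 4))
        return FeatureSet(empty, np.empty((0, 256), dtype=bool))
    kp = np.column_stack([
        orb.keypoints[:, 1],  # x = col
        orb.keypoints[:, 0],  # y = row
        orb.scales,
        orb.orientations,
    ])
    return FeatureSet(kp, orb.descriptors)


def _quad_is_convex(corners: np.ndarray) -> bool:
    c = np.asarray(corners, dtype=float)
    cross = []
    for i in range(4):
        u = c[(i + 1) % 4] - c[i]
        v = c[(i + 2) % 4] - c[(i + 1) % 4]
        cross.append(u[0] * v[1] - u[1] * v[0])
    cross = np.array(cross)
    return bool(np.all(cross > 0) or np.all(cross < 0))


def _quad_area(corners: np.ndarray) -> float:
    c = np.asarray(corners, dtype=float)
    x, y = c[:, 0], c[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _refine_homography(scene: np.ndarray, feat_t: FeatureSet,
                       model: ProjectiveTransform, shape: tuple[int, int],
                       cfg: MatchingConfig) -> ProjectiveTransform:
    """Coarse-to-fine pass: warp the scene into the canonical frame with the
    initial homography, re-match features under a small spatial gate and
    compose a corrective homography. The gate (default 10 px) is under half
    the swatch pitch, so the correction cannot re-lock onto a shifted grid
    position; ORB corner jitter averages out over the gated matches."""
    rect0 = warp(_to_gray(scene), model.inverse, output_shape=shape,
                 order=1, mode="edge")
    feat_r = extract_features(rect0, cfg.max_features)
    if len(feat_r) < 4:
        return model
    matches = match_descriptors(feat_t.descriptors, feat_r.descriptors,
                                metric="hamming", cross_check=False)
    src = feat_r.keypoints[matches[:, 1], :2]   # rectified frame
    dst = feat_t.keypoints[matches[:, 0], :2]   # canonical frame
    close = np.linalg.norm(src - dst, axis=1) <= cfg.refine_radius_px
    if close.sum() < 8:
        return model
    try:
        correction, inl = ransac(
            (src[close], dst[close]), ProjectiveTransform, min_samples=4,
            residual_threshold=cfg.refine_threshold_px,
            max_trials=500, rng=cfg.seed)
    except ValueError:
        return model
    if correction is None or inl is None or inl.sum() < 8:
        return model
    if not np.isfinite(correction.params).all():
        return model
    return model + correction  # scene -> rect0 -> canonical


def detect_and_rectify(scene: np.ndarray, template: np.ndarray,
                       config: MatchingConfig | None = None,
                       ) -> tuple[DetectedObject, np.ndarray]:
    """Locate ``template`` in ``scene`` and warp the scene into its frame.

    Returns the detection result and the rectified color image at the
    template's size. Raises :class:`DetectionFailure` (with match-count
    diagnostics) when there is nothing reliable to match.
    """
    cfg = config or MatchingConfig()
    feat_t = extract_features(template, cfg.max_features)
    feat_s = extract_features(scene, cfg.max_features)
    if len(feat_t) < 4 or len(feat_s) < 4:
        raise DetectionFailure("too few keypoints", 0, 0)

    matches = match_descriptors(feat_t.descriptors, feat_s.descriptors,
                                metric="hamming", cross_check=False)
    # sort all matches by Hamming distance, keep the best
    dist = (feat_t.descriptors[matches[:, 0]]
            != feat_s.descriptors[matches[:, 1]]).mean(axis=1)
    order = np.argsort(dist, kind="stable")[:cfg.matches_kept]
    matches = matches[order]
    n_kept = len(matches)
    if n_kept < cfg.min_matches:
        raise DetectionFailure("too few matches", n_kept, 0)

    src = feat_s.keypoints[matches[:, 1], :2]   # scene xy
    dst = feat_t.keypoints[matches[:, 0], :2]   # canonical xy
    try:
        model, inliers = ransac(
            (src, dst), ProjectiveTransform, min_samples=4,
            residual_threshold=cfg.ransac_threshold_px,
            max_trials=1000, rng=cfg.seed)
    except ValueError as exc:
        raise DetectionFailure(f"homography estimation failed: {exc}",
                               n_kept, 0) from exc
    if model is None or inliers is None:
        raise DetectionFailure("no consensus homography", n_kept, 0)
    n_inliers = int(inliers.sum())
    if n_inliers < cfg.min_inliers:
        raise DetectionFailure("too few inliers", n_kept, n_inliers)

    th, tw = template.shape[:2]
    canonical = np.array([[0, 0], [tw, 0], [tw, th], [0, th]], dtype=float)
    if cfg.refine:
        model = _refine_homography(scene, feat_t, model, (th, tw), cfg)
    H = model.params  # scene -> canonical
    if not np.isfinite(H).all() or abs(np.linalg.det(H)) < 1e-12:
        raise DetectionFailure("degenerate homography", n_kept, n_inliers)
    corners = model.inverse(canonical)
    if not _quad_is_convex(corners):
        raise DetectionFailure("non-convex quad", n_kept, n_inliers)
    scene_area = scene.shape[0] * scene.shape[1]
    if _quad_area(corners) < cfg.min_area_frac * scene_area:
        raise DetectionFailure("quad too small", n_kept, n_inliers)

    scene_f = np.asarray(scene, dtype=np.float64)
    if scene_f.max() > 1.0:
        scene_f = scene_f / 255.0
    rectified = warp(scene_f, model.inverse, output_shape=(th, tw), order=1,
                     mode="edge")
    rectified = (np.clip(rectified, 0, 1) * 255).round().astype(np.uint8)
    obj = DetectedObject(corners=corners, homography=H / H[2, 2],
                         n_matches_kept=n_kept, n_inliers=n_inliers)
    return obj, rectified
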