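"""Field extraction: reference swatches by constant coordinates, test pads
by edge detection, square filtering, k-means clustering and grid completion.

The rectified reference card has a fixed geometry, so its swatches are
simply cropped at the layout's coordinates (scaled to the actual image
size). The strip is less cooperative: pad positions drift with the crop, so
they are found bottom-up. The strip crop is preprocessed under a small grid
of blur/threshold/edge settings; every setting contributes contour-derived
quadrilaterals that look like pads (near-unit aspect ratio, side comparable
to the image height). Candidate centers from all settings are pooled and
clustered with k-means, the cluster count chosen by the elbow rule on the
within-cluster sum of squares. Finally the cluster centers are projected on
the strip's principal axis and gaps larger than 1.5x the median spacing are
filled in, so pads whose contours were too faint to detect still get a
sampling location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans
from skimage.color import rgb2gray, rgb2hsv
from skimage.feature import canny
from skimage.filters import gaussian, threshold_local, threshold_otsu
from skimage.measure import approximate_polygon, find_contours, label, regionprops

from .errors import FieldDetectionFailure, GridCompletionFailure
from .layout import StripLayout

Rect = tuple[int, int, int, int]


@dataclass(frozen=True)
class FieldPatch:
    """A cropped color patch with its provenance."""
    pixels: np.ndarray
    origin: Rect                    # (x, y, w, h) in the source frame
    role: str                       # "test-field" | "reference-field"
    parameter: str
    level: Optional[str] = None     # None for test fields


@dataclass(frozen=True)
class SquareCandidate:
    corners: np.ndarray             # (4, 2) xy
    center: tuple[float, float]
    side: float                     # mean side length, px
    aspect: float                   # long/short side, >= 1


@dataclass(frozen=True)
class FieldGrid:
    centers: np.ndarray             # (expected_count, 2) xy, ordered along axis
    axis: np.ndarray                # unit vector of the strip's long axis
    pitch: float                    # median center spacing, px
    n_inserted: int


@dataclass(frozen=True)
class PreprocessConfig:
    """The preprocessing grid for candidate-square detection.

    Every combination of a blur level and a binarization method is run and
    the surviving quadrilaterals pooled; duplicates across settings are kept
    on purpose, they weight the subsequent clustering toward consistently
    detected pads.
    """
    blur_sigmas: tuple[float, ...] = (0.0, 1.0, 5 / 3, 7 / 3)
    binarizers: tuple[str, ...] = ("otsu", "adaptive", "canny", "sat-otsu",
                                   "rgb-otsu")
    adaptive_block: int = 35
    canny_sigma: float = 1.0
    canny_low: float = 50 / 255
    canny_high: float = 150 / 255
    approx_tol_frac: float = 0.02   # polygon tolerance, fraction of perimeter
    aspect_tol: float = 0.06        # squares: aspect within 1 +/- 0.06
    min_side_frac: float = 0.2      # min side as fraction of image height


# ---------------------------------------------------------------------------
# reference card: constant coordinates
# ---------------------------------------------------------------------------

def extract_reference_fields(rectified_card: np.ndarray,
                             layout: StripLayout) -> list[FieldPatch]:
    """Crop every reference swatch from a rectified card image.

    Coordinates come from the layout's canonical frame, scaled to the
    actual image size; only the central 50 percent of each swatch is kept,
    which avoids border bleed from imperfect rectification.
    """
    img = np.asarray(rectified_card)
    h, w = img.shape[:2]
    if h < 10 or w < 10:
        raise ValueError(f"rectified card too small: {w}x{h}")
    cw, ch = layout.card_size
    sx, sy = w / cw, h / ch
    patches: list[FieldPatch] = []
    for p in layout.parameters:
        for lv in p.levels:
            x, y, rw, rh = layout.card_rect(p.name, lv.label)
            # central 50% of the scaled rectangle
            x0 = int(round((x + rw / 4) * sx))
            x1 = int(round((x + 3 * rw / 4) * sx))
            y0 = int(round((y + rh / 4) * sy))
            y1 = int(round((y + 3 * rh / 4) * sy))
            x1, y1 = max(x1, x0 + 1), max(y1, y0 + 1)
            patches.append(FieldPatch(
                pixels=img[y0:y1, x0:x1],
                origin=(x0, y0, x1 - x0, y1 - y0),
                role="reference-field", parameter=p.name, level=lv.label))
    return patches


# ---------------------------------------------------------------------------
# candidate squares
# ---------------------------------------------------------------------------

def _binarize(gray: np.ndarray, method: str, cfg: PreprocessConfig) -> list[np.ndarray]:
    """Return one or more binary masks for a given method; both polarities
    are produced for the threshold methods, since pads may be darker or
    lighter than their surroundings. ``gray`` is the luminance image except
    for the ``sat-otsu`` setting, which receives the saturation channel
    (colored pads on a near-white strip can be luminance-isoluminant with
    the backing but always stand out in saturation)."""
    if method in ("otsu", "sat-otsu", "rgb-otsu"):
        if gray.std() < 1e-6:
            return []
        t = threshold_otsu(gray)
        return [gray < t, gray > t]
    if method == "adaptive":
        if gray.std() < 1e-6:
            return []
        block = min(cfg.adaptive_block,
                    max(3, (min(gray.shape) // 2) * 2 - 1))
        t = threshold_local(gray, block_size=block, method="mean")
        return [gray < t, gray > t]
    if method == "canny":
        edges = canny(gray, sigma=cfg.canny_sigma,
                      low_threshold=cfg.canny_low,
                      high_threshold=cfg.canny_high)
        return [ndimage.binary_fill_holes(edges)]
    raise ValueError(f"unknown binarizer {method!r}")


def _quad_from_region(mask: np.ndarray, tol_frac: float) -> Optional[np.ndarray]:
    """Approximate a region's boundary by a polygon; return the 4 corners
    as xy if it reduces to a convex quadrilateral, else None. The polygon
    tolerance is escalated (1x, 2x, 3x the base fraction of the perimeter)
    because noise nibs on a pad's edge survive small tolerances."""
    padded = np.pad(mask, 1)
    contours = find_contours(padded.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    perimeter = np.sum(np.linalg.norm(np.diff(contour, axis=0), axis=1))
    for tol in (tol_frac, 2 * tol_frac, 3 * tol_frac):
        poly = approximate_polygon(contour, tolerance=tol * perimeter)
        if len(poly) > 1 and np.allclose(poly[0], poly[-1]):
            poly = poly[:-1]
        if len(poly) != 4:
            continue
        quad = poly[:, ::-1] - 1.0  # (row, col) -> (x, y), undo padding
        cross = []
        for i in range(4):
            u = quad[(i + 1) % 4] - quad[i]
            v = quad[(i + 2) % 4] - quad[(i + 1) % 4]
            cross.append(u[0] * v[1] - u[1] * v[0])
        cross = np.asarray(cross)
        if np.all(cross > 0) or np.all(cross < 0):
            return quad
    return None


def find_candidate_squares(strip_image: np.ndarray,
                           config: PreprocessConfig | None = None,
                           ) -> list[SquareCandidate]:
    """Detect square-like pad candidates under the preprocessing grid.

    A candidate must be a convex quadrilateral with aspect ratio within
    1 +/- 0.06 and side length at least 0.2x the image height. The union
    over all settings is returned; an empty list is a valid outcome.
    """
    cfg = config or PreprocessConfig()
    img = np.asarray(strip_image)
    if img.ndim == 3:
        imgf = img.astype(float) / 255.0 if img.max() > 1.0 else img
        gray = rgb2gray(imgf)
        # chromatic pads can be isoluminant with the strip backing but
        # always stand out in saturation or in a single RGB channel
        extra = {"sat-otsu": [rgb2hsv(imgf)[..., 1]],
                 "rgb-otsu": [imgf[..., c] for c in range(3)]}
    else:
        gray = img.astype(float)
        if gray.max() > 1.0:
            gray = gray / 255.0
        extra = {}
    # "image height" in the side filter means the strip's transverse extent:
    # for a portrait (rotated) crop that is the width, hence min(h, w)
    h = min(gray.shape[0], gray.shape[1])
    min_side = cfg.min_side_frac * h
    min_area = min_side ** 2
    out: list[SquareCandidate] = []
    for sigma in cfg.blur_sigmas:
        for method in cfg.binarizers:
            channels = extra.get(method, [gray]) if method in (
                "sat-otsu", "rgb-otsu") else [gray]
            if method in ("sat-otsu", "rgb-otsu") and not extra:
                continue
            masks = []
            for chan in channels:
                g = gaussian(chan, sigma=sigma) if sigma > 0 else chan
                masks.extend(_binarize(g, method, cfg))
            for binary in masks:
                labels = label(binary)
                for region in regionprops(labels):
                    if region.area < 0.5 * min_area:
                        continue
                    if region.area > 0.95 * gray.size:
                        continue
                    minr, minc, maxr, maxc = region.bbox
                    quad = _quad_from_region(region.image, cfg.approx_tol_frac)
                    if quad is None:
                        continue
                    quad = quad + np.array([minc, minr], dtype=float)
                    sides = np.linalg.norm(np.diff(
                        np.vstack([quad, quad[:1]]), axis=0), axis=1)
                    if sides.min() <= 0:
                        continue
                    # average opposite sides: single-pixel contour jitter on
                    # one edge should not decide the aspect
                    wh = np.array([(sides[0] + sides[2]) / 2,
                                   (sides[1] + sides[3]) / 2])
                    aspect = wh.max() / wh.min()
                    if aspect > 1 + cfg.aspect_tol:
                        continue
                    if wh.min() < min_side:
                        continue
                    center = quad.mean(axis=0)
                    out.append(SquareCandidate(
                        corners=quad, center=(float(center[0]), float(center[1])),
                        side=float(sides.mean()), aspect=float(aspect)))
    return out


# ---------------------------------------------------------------------------
# clustering with elbow-selected k
# ---------------------------------------------------------------------------

def _fit_kmeans(points: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points trigger a warning
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(points)
    return km.cluster_centers_, float(km.inertia_)


def cluster_field_centers(points: Sequence[tuple[float, float]],
                          k_max: int, seed: int) -> np.ndarray:
    """Cluster candidate centers with k-means; k chosen by the elbow rule.

    The within-cluster sum of squares (WCSS) is computed for
    k = 1..min(k_max, #distinct points) and k is chosen to maximize the
    second difference of the log-WCSS curve; ties break toward smaller k.
    The log scale is what makes this a bend detector: raw WCSS of spread-out
    cluster arrangements decays convexly in k, so its plain second
    difference peaks at k=2 regardless of the true cluster count, whereas
    log-WCSS drops sharply exactly where k reaches the number of tight
    blobs. Deterministic given the seed.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("points must be non-empty")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    n_distinct = len(np.unique(pts, axis=0))
    k_hi = min(k_max, n_distinct)
    if k_hi == 1:
        return pts.mean(axis=0, keepdims=True)
    results = {}
    wcss = np.empty(k_hi + 1)
    for k in range(1, k_hi + 1):
        centers, inertia = _fit_kmeans(pts, k, seed)
        results[k] = centers
        wcss[k] = inertia
    if k_hi >= 3:
        floor = max(wcss[1] * 1e-9, 1e-12)  # log-safe for zero-inertia fits
        wl = np.log(np.maximum(wcss, floor))
        ks = np.arange(2, k_hi)
        d2 = wl[ks - 1] - 2 * wl[ks] + wl[ks + 1]
        k_best = int(ks[np.argmax(d2)])  # argmax keeps the smallest on ties
    else:  # only k in {1, 2} available: bend undefined, prefer the smaller
        k_best = 1 if wcss[1] <= 1e-12 else 2
    centers = results[k_best]
    order = np.lexsort((centers[:, 1], centers[:, 0]))
    return centers[order]


# ---------------------------------------------------------------------------
# grid completion
# ---------------------------------------------------------------------------

def _principal_axis(pts: np.ndarray) -> np.ndarray:
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    # deterministic sign: dominant component positive
    i = int(np.argmax(np.abs(axis)))
    if axis[i] < 0:
        axis = -axis
    return axis


def complete_field_grid(centers: Sequence[tuple[float, float]],
                        expected_count: int,
                        bounds: Optional[tuple[int, int]] = None) -> FieldGrid:
    """Order detected centers along the strip axis and fill in missing pads.

    Centers are projected onto their principal axis and sorted; the pitch
    is the median consecutive spacing. Any gap wider than 1.5x the pitch is
    filled with round(gap/pitch) - 1 equally spaced points. If the grid is
    still short of ``expected_count``, points are extrapolated by one pitch
    beyond the ends, alternating and starting at the dipped end (the low
    end of the ordering); with ``bounds`` (image width, height) given, an
    end whose next point would fall outside the image is skipped in favor
    of the other end — pads cannot lie outside the crop. Needing to
    extrapolate more than half the expected count is treated as a failure
    rather than guessed through.
    """
    pts = np.asarray(centers, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise ValueError("need at least 2 centers")
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate centers: all points coincide")
    if expected_count < len(pts):
        raise GridCompletionFailure(
            f"{len(pts)} centers exceed expected_count={expected_count}")
    axis = _principal_axis(pts)

    def _project(p: np.ndarray):
        t = (p - p.mean(axis=0)) @ axis
        order = np.argsort(t, kind="stable")
        return p[order], t[order]

    def _pitch_of(gaps: np.ndarray) -> float:
        """Median spacing, robust to skipped pads: a gap spanning several
        missing pads is divided by its rounded multiple of the smallest
        gap before taking the median."""
        g0 = gaps.min()
        if g0 <= 1e-9:
            return float(np.median(gaps))
        mult = np.maximum(1, np.round(gaps / g0))
        return float(np.median(gaps / mult))

    pts, t = _project(pts)
    # merge near-duplicate centers (two clusters landing on one pad)
    while len(pts) > 2:
        gaps = np.diff(t)
        pitch = float(np.median(gaps))
        close = np.flatnonzero(gaps < 0.5 * pitch)
        if pitch <= 1e-9 or len(close) == 0:
            break
        i = int(close[0])
        merged = (pts[i] + pts[i + 1]) / 2
        pts = np.vstack([pts[:i], [merged], pts[i + 2:]])
        pts, t = _project(pts)
    gaps = np.diff(t)
    pitch = _pitch_of(gaps)
    if pitch <= 1e-9:
        raise ValueError("degenerate spacing: zero median pitch")

    filled = [pts[0]]
    n_inserted = 0
    for i in range(len(pts) - 1):
        gap = gaps[i]
        if gap > 1.5 * pitch:
            m = max(int(round(gap / pitch)) - 1, 1)
            for j in range(1, m + 1):
                filled.append(pts[i] + (pts[i + 1] - pts[i]) * j / (m + 1))
            n_inserted += m
        filled.append(pts[i + 1])
    grid = np.asarray(filled)
    if len(grid) > expected_count:
        raise GridCompletionFailure(
            f"gap filling produced {len(grid)} centers, "
            f"expected {expected_count}")

    n_extra = expected_count - len(grid)
    if n_extra > expected_count / 2:
        raise GridCompletionFailure(
            f"would need {n_extra} extrapolated centers "
            f"for expected_count={expected_count}")
    def _inside(p: np.ndarray) -> bool:
        if bounds is None:
            return True
        bw, bh = bounds
        return 0 <= p[0] < bw and 0 <= p[1] < bh

    at_start = True  # dipped end first
    for _ in range(n_extra):
        lo = grid[0] - axis * pitch
        hi = grid[-1] + axis * pitch
        use_start = at_start if _inside(lo) == _inside(hi) else _inside(lo)
        if not (_inside(lo) or _inside(hi)):
            raise GridCompletionFailure(
                "cannot extrapolate: both ends leave the image bounds")
        grid = np.vstack([lo, grid]) if use_start else np.vstack([grid, hi])
        if use_start == at_start:
            at_start = not at_start
        n_inserted += 1
    # snap centers onto the fitted strip midline: pads are collinear, so a
    # transverse offset on one detected center is clutter, not signal
    mean = pts.mean(axis=0)
    grid = mean + np.outer((grid - mean) @ axis, axis)
    return FieldGrid(centers=grid, axis=axis, pitch=pitch,
                     n_inserted=n_inserted)


# ---------------------------------------------------------------------------
# full strip localization
# ---------------------------------------------------------------------------

def locate_test_fields(strip_image: np.ndarray, layout: StripLayout,
                       seed: int = 0,
                       config: PreprocessConfig | None = None,
                       ) -> list[FieldPatch]:
    """Find the strip's test pads and crop a sampling patch for each.

    Composition of :func:`find_candidate_squares`,
    :func:`cluster_field_centers` and :func:`complete_field_grid`; each
    completed grid center gets a square patch of half the median candidate
    side, and patches are assigned to the layout's parameters in order
    along the axis from the dipped end (assumed to be the low-coordinate
    end of the crop).
    """
    img = np.asarray(strip_image)
    candidates = find_candidate_squares(img, config)
    if len(candidates) < 2:
        raise FieldDetectionFailure(
            f"only {len(candidates)} candidate squares found")
    points = np.array([c.center for c in candidates])
    expected = layout.expected_count
    centers = cluster_field_centers(points, k_max=expected + 2, seed=seed)
    if len(centers) > expected:
        centers, _ = _fit_kmeans(points, expected, seed)
    if len(centers) < 2:
        raise FieldDetectionFailure("clustering collapsed to a single center")
    grid = complete_field_grid(centers, expected,
                               bounds=(img.shape[1], img.shape[0]))

    side = 0.5 * float(np.median([c.side for c in candidates]))
    half = max(1, int(round(side / 2)))
    h, w = img.shape[:2]
    patches: list[FieldPatch] = []
    for param, (cx, cy) in zip(layout.parameters, grid.centers):
        x0 = int(np.clip(round(cx) - half, 0, w - 1))
        y0 = int(np.clip(round(cy) - half, 0, h - 1))
        x1 = int(np.clip(round(cx) + half, x0 + 1, w))
        y1 = int(np.clip(round(cy) + half, y0 + 1, h))
        patches.append(FieldPatch(
            pixels=img[y0:y1, x0:x1], origin=(x0, y0, x1 - x0, y1 - y0),
            role="test-field", parameter=param.name))
    return patches
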