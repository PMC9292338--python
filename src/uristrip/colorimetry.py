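"""Histogram-peak color extraction and HSV color-similarity measures.

Each field patch (test pad or reference swatch) is reduced to a single
dominant color: the image is converted to HSV and, per channel, the peak of
the channel histogram is taken. Two dominant colors are then compared with
one of three similarity measures, all mapped to [0, 1] where 1 is identity:

``hue``
    ``1 - dH / H_max`` with ``H_max = 360`` degrees. Hue differences are
    circular (wrap-around), so ``dH <= 180`` and the score lies in
    [0.5, 1] for chromatic colors.

``matching_factor``
    ``1 - (a*dH + b*dS + b*dV) / (H_max + S_max + V_max)`` with the weights
    ``a = 0.6429`` and ``b = 0.1786``. Channels are unit-normalized
    (``H_max = S_max = V_max = 1``, with the circular hue difference divided
    by 360 before weighting) so each weighted term is bounded by its weight
    and the score stays within [0, 1].

``euclidean``
    HSV read as cylinder coordinates ``(s*cos h, s*sin h, v)``; the score is
    ``1 - d / sqrt((2*S_max)^2 + V_max^2)``, i.e. the chord through the
    cylinder normalized by the largest possible distance ``sqrt(5)``.

The matched level of a test pad is simply the reference level whose
dominant color maximizes the chosen similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage.color import rgb2hsv

from .layout import Level

#: Hue weight and saturation/value weight of the matching factor.
ALPHA = 0.6429
BETA = 0.1786

#: Below this saturation a color is treated as achromatic: its hue channel
#: is numerically meaningless.
ACHROMATIC_S = 0.05

#: Histogram bin counts per channel (hue in degrees, s and v in [0, 1]).
H_BINS, S_BINS, V_BINS = 360, 256, 256

METHODS = ("hue", "matching_factor", "euclidean")

_EUCLID_NORM = np.sqrt(5.0)  # sqrt((2*S_max)^2 + V_max^2) with S_max=V_max=1


@dataclass(frozen=True)
class HsvPeak:
    """Dominant color of a patch: hue in degrees [0, 360), s and v in [0, 1].

    By convention the hue of an achromatic color (s below the guard
    threshold) is reported as 0.
    """
    h: float
    s: float
    v: float


@dataclass(frozen=True)
class SimilarityScore:
    method: str
    value: float


def _as_pixels(patch) -> np.ndarray:
    """Accept a FieldPatch or a raw H x W x 3 array; return float RGB in [0,1]."""
    px = getattr(patch, "pixels", patch)
    px = np.asarray(px)
    if px.ndim != 3 or px.shape[2] != 3 or px.size == 0:
        raise ValueError("patch must be a non-empty H x W x 3 color array")
    if px.dtype == np.uint8:
        return px.astype(np.float64) / 255.0
    return np.clip(px.astype(np.float64), 0.0, 1.0)


def hsv_peak(patch) -> HsvPeak:
    """Dominant HSV color of a patch by per-channel histogram peak.

    Hue uses 360 one-degree bins, saturation and value 256 bins each; the
    returned value is the peak bin's center, ties broken toward the lowest
    bin. Achromatic patches (peak saturation < 0.05) report hue 0.
    """
    hsv = rgb2hsv(_as_pixels(patch))
    h = hsv[..., 0].ravel() * 360.0
    s = hsv[..., 1].ravel()
    v = hsv[..., 2].ravel()
    h_hist, _ = np.histogram(h, bins=H_BINS, range=(0.0, 360.0))
    s_hist, _ = np.histogram(s, bins=S_BINS, range=(0.0, 1.0))
    v_hist, _ = np.histogram(v, bins=V_BINS, range=(0.0, 1.0))
    # np.argmax returns the first (lowest) bin on ties
    h_pk = (int(np.argmax(h_hist)) + 0.5) * (360.0 / H_BINS)
    s_pk = (int(np.argmax(s_hist)) + 0.5) / S_BINS
    v_pk = (int(np.argmax(v_hist)) + 0.5) / V_BINS
    if s_pk < ACHROMATIC_S:
        h_pk = 0.0
    return HsvPeak(h=h_pk, s=s_pk, v=v_pk)


def circular_hue_difference(h_a: float, h_b: float) -> float:
    """Wrap-around hue difference in degrees, in [0, 180]."""
    d = abs(h_a - h_b) % 360.0
    return min(d, 360.0 - d)


def similarity_hue(a: HsvPeak, b: HsvPeak, *,
                   achromatic_guard: bool = True) -> SimilarityScore:
    """Hue-channel similarity ``1 - dH/360`` with circular dH.

    When either color is achromatic (s < 0.05) the hue channel carries no
    information; with ``achromatic_guard`` on (the default) the score falls
    back to the matching factor restricted to its saturation and value
    terms. This guard is an extension beyond the plain hue comparison and
    can be disabled.
    """
    if achromatic_guard and (a.s < ACHROMATIC_S or b.s < ACHROMATIC_S):
        val = 1.0 - (BETA * abs(a.s - b.s) + BETA * abs(a.v - b.v)) / 3.0
        return SimilarityScore("hue", float(val))
    d = circular_hue_difference(a.h, b.h)
    return SimilarityScore("hue", float(1.0 - d / 360.0))


def similarity_matching_factor(a: HsvPeak, b: HsvPeak) -> SimilarityScore:
    """Weighted HSV matching factor with unit-normalized channels."""
    dh = circular_hue_difference(a.h, b.h) / 360.0
    ds = abs(a.s - b.s)
    dv = abs(a.v - b.v)
    val = 1.0 - (ALPHA * dh + BETA * ds + BETA * dv) / 3.0
    return SimilarityScore("matching_factor", float(val))


def _cylinder(p: HsvPeak) -> np.ndarray:
    th = np.deg2rad(p.h)
    return np.array([p.s * np.cos(th), p.s * np.sin(th), p.v])


def similarity_euclidean(a: HsvPeak, b: HsvPeak) -> SimilarityScore:
    """Euclidean similarity in HSV cylinder coordinates, normalized by
    the cylinder's diameter-height diagonal sqrt(5)."""
    d = float(np.linalg.norm(_cylinder(a) - _cylinder(b)))
    return SimilarityScore("euclidean", float(1.0 - d / _EUCLID_NORM))


_SIM_FUNCS = {
    "hue": similarity_hue,
    "matching_factor": similarity_matching_factor,
    "euclidean": similarity_euclidean,
}


def similarity(a: HsvPeak, b: HsvPeak, method: str, *,
               achromatic_guard: bool = True) -> SimilarityScore:
    """Dispatch to one of the three similarity measures by name."""
    if method == "hue":
        return similarity_hue(a, b, achromatic_guard=achromatic_guard)
    try:
        return _SIM_FUNCS[method](a, b)
    except KeyError:
        raise ValueError(f"unknown similarity method {method!r}; "
                         f"expected one of {METHODS}") from None


def determine_result(test: HsvPeak,
                     references: Sequence[tuple[Level, HsvPeak]],
                     method: str, *,
                     achromatic_guard: bool = True,
                     ) -> tuple[Level, SimilarityScore]:
    """Match a test pad's color to the most similar reference level.

    ``references`` must be ordered from lowest to highest
    concentration/severity; ties break toward the lowest level (strict
    improvement required to move up).
    """
    if not references:
        raise ValueError("references must be non-empty")
    if method not in METHODS:
        raise ValueError(f"unknown similarity method {method!r}")
    best: tuple[Level, SimilarityScore] | None = None
    for level, ref_peak in references:
        score = similarity(test, ref_peak, method,
                           achromatic_guard=achromatic_guard)
        if best is None or score.value > best[1].value:
            best = (level, score)
    return best
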