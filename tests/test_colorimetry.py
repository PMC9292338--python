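"""Histogram-peak extraction and the three HSV similarity measures."""

import colorsys

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uristrip import (HsvPeak, determine_result, hsv_peak, similarity_hue,
                      similarity_euclidean, similarity_matching_factor)
from uristrip.colorimetry import ALPHA, BETA, METHODS, similarity
from uristrip.layout import Level


def _const_patch(rgb, shape=(20, 20)):
    return np.full(shape + (3,), rgb, dtype=np.uint8)


def _mode_oracle(patch):
    """Independent per-channel mode via direct pixel counting."""
    hsv = np.array([colorsys.rgb_to_hsv(*px)
                    for px in patch.reshape(-1, 3) / 255.0])
    h_bins = np.clip((hsv[:, 0] * 360).astype(int), 0, 359)
    s_bins = np.clip((hsv[:, 1] * 256).astype(int), 0, 255)
    v_bins = np.clip((hsv[:, 2] * 256).astype(int), 0, 255)
    return (np.bincount(h_bins, minlength=360).argmax() + 0.5,
            (np.bincount(s_bins, minlength=256).argmax() + 0.5) / 256,
            (np.bincount(v_bins, minlength=256).argmax() + 0.5) / 256)


def test_pure_red_peak():
    peak = hsv_peak(_const_patch((255, 0, 0)))
    assert peak.h <= 1.0          # within one hue bin of 0 degrees
    assert peak.s > 1 - 1 / 256
    assert peak.v > 1 - 1 / 256


def test_majority_color_wins():
    patch = np.empty((10, 10, 3), np.uint8)
    patch[:7] = (30, 200, 60)   # 70 percent
    patch[7:] = (200, 30, 60)   # 30 percent
    peak = hsv_peak(patch)
    oh, os_, ov = _mode_oracle(np.full((1, 1, 3), (30, 200, 60), np.uint8))
    assert abs(peak.h - oh) < 1e-9
    assert abs(peak.s - os_) < 1e-9
    assert abs(peak.v - ov) < 1e-9


def test_even_split_ties_to_lower_bin():
    patch = np.empty((10, 10, 3), np.uint8)
    patch[:5] = (200, 60, 60)     # hue 0
    patch[5:] = (60, 200, 60)     # hue 120
    peak = hsv_peak(patch)
    assert peak.h < 1.0           # the lower hue bin wins the tie


def test_achromatic_patch_reports_zero_hue():
    peak = hsv_peak(_const_patch((128, 128, 128)))
    assert peak.h == 0.0
    assert peak.s < 0.05


def test_empty_patch_rejected():
    with pytest.raises(ValueError):
        hsv_peak(np.empty((0, 0, 3), np.uint8))


def test_peak_matches_mode_oracle_on_random_patches(rng):
    for _ in range(50):
        patch = rng.integers(0, 256, size=(12, 12, 3), dtype=np.uint8)
        peak = hsv_peak(patch)
        oh, os_, ov = _mode_oracle(patch)
        if peak.s >= 0.05:        # achromatic convention rewrites hue
            assert abs(peak.h - oh) < 1e-9
        assert abs(peak.s - os_) < 1e-9
        assert abs(peak.v - ov) < 1e-9


# ---------------------------------------------------------------------------
# closed-form similarity values
# ---------------------------------------------------------------------------

def test_hue_similarity_closed_forms():
    a = HsvPeak(0.0, 0.8, 0.8)
    assert similarity_hue(a, a).value == 1.0
    opposite = HsvPeak(180.0, 0.8, 0.8)
    assert similarity_hue(a, opposite).value == pytest.approx(0.5)
    wrap = similarity_hue(HsvPeak(350.0, 0.8, 0.8), HsvPeak(10.0, 0.8, 0.8))
    assert wrap.value == pytest.approx(1 - 20 / 360)  # ~0.9444


def test_hue_similarity_ignores_saturation_and_value():
    a, b = HsvPeak(40.0, 0.9, 0.2), HsvPeak(90.0, 0.3, 0.8)
    base = similarity_hue(a, b).value
    for s, v in [(0.1, 0.9), (0.5, 0.5), (1.0, 0.1)]:
        assert similarity_hue(HsvPeak(40.0, s, v), b).value == base


def test_achromatic_guard_falls_back_to_sv_terms():
    gray = HsvPeak(0.0, 0.0, 0.5)
    color = HsvPeak(200.0, 0.6, 0.9)
    guarded = similarity_hue(gray, color).value
    assert guarded == pytest.approx(1 - (BETA * 0.6 + BETA * 0.4) / 3)
    raw = similarity_hue(gray, color, achromatic_guard=False).value
    assert raw == pytest.approx(1 - 160 / 360)  # circular dH(0, 200) = 160


def test_matching_factor_closed_forms():
    a = HsvPeak(10.0, 0.4, 0.6)
    assert similarity_matching_factor(a, a).value == 1.0
    # maximal circular hue difference, no s/v difference
    half = similarity_matching_factor(HsvPeak(0, 0.5, 0.5),
                                      HsvPeak(180, 0.5, 0.5))
    assert half.value == pytest.approx(1 - ALPHA * 0.5 / 3)  # ~0.8929
    # full saturation difference only
    sat = similarity_matching_factor(HsvPeak(90, 0.0, 0.5),
                                     HsvPeak(90, 1.0, 0.5))
    assert sat.value == pytest.approx(1 - BETA / 3)  # ~0.9405


def test_euclidean_closed_forms():
    a = HsvPeak(123.0, 0.3, 0.7)
    assert similarity_euclidean(a, a).value == 1.0
    worst = similarity_euclidean(HsvPeak(0, 1, 0), HsvPeak(180, 1, 1))
    assert worst.value == pytest.approx(0.0, abs=1e-12)
    dv = 0.4
    grays = similarity_euclidean(HsvPeak(0, 0, 0.2), HsvPeak(0, 0, 0.2 + dv))
    assert grays.value == pytest.approx(1 - dv / np.sqrt(5))


# ---------------------------------------------------------------------------
# metric properties
# ---------------------------------------------------------------------------

peaks = st.builds(HsvPeak,
                  h=st.floats(0, 359.999),
                  s=st.floats(0, 1),
                  v=st.floats(0, 1))


@settings(max_examples=300, derandomize=True)
@given(a=peaks, b=peaks, method=st.sampled_from(METHODS))
def test_similarity_symmetric_bounded_and_reflexive(a, b, method):
    ab = similarity(a, b, method).value
    ba = similarity(b, a, method).value
    assert ab == pytest.approx(ba, abs=1e-12)
    assert 0.0 <= ab <= 1.0 + 1e-12
    assert similarity(a, a, method).value == 1.0


# ---------------------------------------------------------------------------
# result determination
# ---------------------------------------------------------------------------

def _ref_levels(hues, s=0.7, v=0.8):
    return [(Level(label=f"L{i}", value=float(i), unit="mg/dl",
                   color_rgb=(0, 0, 0)), HsvPeak(h, s, v))
            for i, h in enumerate(hues)]


def test_exact_match_dominates():
    refs = _ref_levels([20, 80, 140, 200])
    level, score = determine_result(HsvPeak(140, 0.7, 0.8), refs, "hue")
    assert level.label == "L2"
    assert score.value == 1.0


def test_tie_breaks_toward_lower_level():
    refs = _ref_levels([40, 80])
    level, _ = determine_result(HsvPeak(60, 0.7, 0.8), refs, "hue")
    assert level.label == "L0"


@pytest.mark.parametrize("method", METHODS)
def test_perturbed_peak_recovers_planted_level(method, rng):
    refs = _ref_levels([10, 50, 90, 130, 170])
    for _ in range(20):
        i = int(rng.integers(5))
        true = refs[i][1]
        noisy = HsvPeak((true.h + rng.normal(0, 5)) % 360, true.s, true.v)
        level, _ = determine_result(noisy, refs, method)
        assert level.label == f"L{i}"


def test_agrees_with_independent_argmax(rng):
    """determine_result equals a separately coded scalar argmax loop."""
    for _ in range(100):
        refs = _ref_levels(rng.uniform(0, 360, size=5),
                           s=float(rng.uniform(0.2, 1)),
                           v=float(rng.uniform(0.2, 1)))
        test = HsvPeak(float(rng.uniform(0, 360)),
                       float(rng.uniform(0.05, 1)),
                       float(rng.uniform(0, 1)))
        for method in METHODS:
            level, score = determine_result(test, refs, method)
            best_i, best_v = 0, -np.inf
            for i, (_, ref) in enumerate(refs):
                dh = min(abs(test.h - ref.h), 360 - abs(test.h - ref.h))
                ds, dv = abs(test.s - ref.s), abs(test.v - ref.v)
                if method == "hue":
                    if test.s < 0.05 or ref.s < 0.05:
                        val = 1 - (BETA * ds + BETA * dv) / 3
                    else:
                        val = 1 - dh / 360
                elif method == "matching_factor":
                    val = 1 - (ALPHA * dh / 360 + BETA * ds + BETA * dv) / 3
                else:
                    ax = (test.s * np.cos(np.radians(test.h)),
                          test.s * np.sin(np.radians(test.h)), test.v)
                    bx = (ref.s * np.cos(np.radians(ref.h)),
                          ref.s * np.sin(np.radians(ref.h)), ref.v)
                    d = np.sqrt(sum((p - q) ** 2 for p, q in zip(ax, bx)))
                    val = 1 - d / np.sqrt(5)
                if val > best_v:
                    best_i, best_v = i, val
            assert level.label == f"L{best_i}"
            assert score.value == pytest.approx(best_v, abs=1e-12)


def test_unknown_method_rejected():
    refs = _ref_levels([0, 120])
    with pytest.raises(ValueError):
        determine_result(HsvPeak(0, 1, 1), refs, "cosine")
    with pytest.raises(ValueError):
        determine_result(HsvPeak(0, 1, 1), [], "hue")
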