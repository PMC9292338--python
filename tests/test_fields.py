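"""Reference-swatch extraction, square detection, clustering, grid completion."""

import itertools

import numpy as np
import pytest

from uristrip import (FieldDetectionFailure, GridCompletionFailure,
                      SceneConfig, cluster_field_centers, complete_field_grid,
                      extract_reference_fields, find_candidate_squares,
                      locate_test_fields, render_scene, render_strip_template)
from uristrip.synthgen import strip_field_rects
from skimage.transform import resize


# ---------------------------------------------------------------------------
# reference fields
# ---------------------------------------------------------------------------

def test_reference_patches_have_exact_template_colors(card_template, layout):
    patches = extract_reference_fields(card_template, layout)
    assert len(patches) == sum(len(p.levels) for p in layout.parameters)
    for patch in patches:
        expected = layout.parameter(patch.parameter).level(patch.level).color_rgb
        assert patch.pixels.size > 0
        np.testing.assert_array_equal(
            patch.pixels.reshape(-1, 3).mean(axis=0), expected)


def test_reference_patches_scale_with_image_size(card_template, layout):
    doubled = (resize(card_template, (card_template.shape[0] * 2,
                                      card_template.shape[1] * 2),
                      order=0, preserve_range=True)).astype(np.uint8)
    for patch in extract_reference_fields(doubled, layout):
        expected = layout.parameter(patch.parameter).level(patch.level).color_rgb
        np.testing.assert_array_equal(
            patch.pixels.reshape(-1, 3).mean(axis=0), expected)


def test_tiny_rectified_image_is_rejected(layout):
    with pytest.raises(ValueError):
        extract_reference_fields(np.zeros((5, 5, 3), np.uint8), layout)


# ---------------------------------------------------------------------------
# candidate squares
# ---------------------------------------------------------------------------

def test_blank_image_has_no_candidates():
    assert find_candidate_squares(np.full((60, 400, 3), 255, np.uint8)) == []


def test_two_to_one_rectangle_fails_aspect_filter():
    img = np.full((100, 300, 3), 255, np.uint8)
    img[30:70, 100:180] = (40, 40, 40)  # 80 x 40 rectangle, aspect 2
    assert find_candidate_squares(img) == []


def test_every_true_pad_is_overlapped_by_a_candidate(layout):
    planted = {p.name: p.levels[-1].label for p in layout.parameters}
    strip = render_strip_template(layout, planted)
    pad = np.pad(strip, ((8, 8), (8, 8), (0, 0)), constant_values=250)
    candidates = find_candidate_squares(pad)
    rects = strip_field_rects(layout)
    for (x, y, w, h) in rects:
        assert any(x <= c.center[0] - 8 <= x + w and
                   y <= c.center[1] - 8 <= y + h
                   for c in candidates)
    assert all(1 <= c.aspect <= 1.06 for c in candidates)
    assert all(c.side >= 0.2 * pad.shape[0] for c in candidates)


# ---------------------------------------------------------------------------
# clustering with elbow-selected k
# ---------------------------------------------------------------------------

def _optimal_partition_wcss(points, k):
    """Exhaustive optimal k-clustering of a small instance."""
    pts = np.asarray(points, float)
    best = (np.inf, None)
    for assign in itertools.product(range(k), repeat=len(pts)):
        if len(set(assign)) != k:
            continue
        w = 0.0
        for c in range(k):
            members = pts[[i for i, a in enumerate(assign) if a == c]]
            w += ((members - members.mean(axis=0)) ** 2).sum()
        if w < best[0]:
            best = (w, assign)
    w, assign = best
    centers = np.array([pts[[i for i, a in enumerate(assign) if a == c]]
                        .mean(axis=0) for c in range(k)])
    return w, centers[np.lexsort((centers[:, 1], centers[:, 0]))]


def _blobs(rng, means, n_per, radius):
    pts = []
    for m in means:
        pts.append(np.asarray(m) + rng.normal(0, radius, size=(n_per, 2)))
    return np.vstack(pts)


def test_three_tight_blobs_recovered_exactly(rng):
    means = [(0, 0), (50, 0), (100, 10)]
    pts = _blobs(rng, means, n_per=10, radius=0.5)
    centers = cluster_field_centers(pts, k_max=6, seed=0)
    assert len(centers) == 3
    _, oracle = _optimal_partition_wcss(pts[::3], 3)  # small sub-instance
    for m in means:
        blob = pts[np.linalg.norm(pts - m, axis=1) < 10]
        assert np.linalg.norm(centers - blob.mean(axis=0), axis=1).min() < 1.0


def test_matches_exhaustive_optimal_clustering(rng):
    """Elbow-selected k-means equals brute-force optimal clustering on a
    small instance."""
    means = [(0, 0), (40, 5), (80, -5)]
    pts = _blobs(rng, means, n_per=3, radius=0.3)  # 9 points, 3 blobs
    centers = cluster_field_centers(pts, k_max=5, seed=0)
    assert len(centers) == 3
    _, oracle_centers = _optimal_partition_wcss(pts, 3)
    np.testing.assert_allclose(centers, oracle_centers, atol=1e-6)


def test_identical_points_collapse_to_one_center():
    pts = np.tile([[7.0, 3.0]], (5, 1))
    centers = cluster_field_centers(pts, k_max=4, seed=0)
    np.testing.assert_allclose(centers, [[7.0, 3.0]])


def test_four_well_separated_blobs_select_k4(rng):
    means = [(0, 0), (60, 0), (0, 60), (60, 60)]
    pts = _blobs(rng, means, n_per=10, radius=0.8)
    centers = cluster_field_centers(pts, k_max=8, seed=0)
    assert len(centers) == 4


def test_clustering_invariant_to_input_order(rng):
    pts = _blobs(rng, [(0, 0), (30, 0), (60, 0)], n_per=8, radius=0.5)
    a = cluster_field_centers(pts, k_max=6, seed=0)
    b = cluster_field_centers(pts[::-1], k_max=6, seed=0)
    np.testing.assert_allclose(a, b, atol=1e-9)


def test_empty_points_rejected():
    with pytest.raises(ValueError):
        cluster_field_centers(np.empty((0, 2)), k_max=3, seed=0)


# ---------------------------------------------------------------------------
# grid completion
# ---------------------------------------------------------------------------

def test_single_gap_insertion():
    centers = [(x, 0.0) for x in (0, 10, 20, 30, 50, 60, 70, 80, 90)]
    grid = complete_field_grid(centers, expected_count=10)
    assert grid.n_inserted == 1
    np.testing.assert_allclose(grid.centers[:, 0], np.arange(0, 100, 10),
                               atol=1e-9)
    np.testing.assert_allclose(grid.pitch, 10.0)


def test_complete_grid_is_noop_when_complete():
    centers = [(x, 0.0) for x in range(0, 100, 10)]
    grid = complete_field_grid(centers, expected_count=10)
    assert grid.n_inserted == 0
    np.testing.assert_allclose(grid.centers[:, 0], np.arange(0, 100, 10))


def test_extrapolation_alternates_ends():
    centers = [(x, 0.0) for x in range(0, 80, 10)]  # 8 pts spanning 0..70
    grid = complete_field_grid(centers, expected_count=10)
    assert grid.n_inserted == 2
    np.testing.assert_allclose(sorted(grid.centers[:, 0]),
                               np.arange(-10, 90, 10), atol=1e-9)


def test_extrapolation_respects_image_bounds():
    centers = [(x, 5.0) for x in range(5, 85, 10)]  # 8 pts, near left edge
    grid = complete_field_grid(centers, expected_count=10, bounds=(200, 20))
    # left end would go to x=-5 (outside) so both go to the right
    np.testing.assert_allclose(sorted(grid.centers[:, 0]),
                               np.arange(5, 105, 10), atol=1e-9)


def test_completion_is_idempotent():
    centers = [(x, 0.0) for x in (0, 10, 20, 50, 60, 90)]
    first = complete_field_grid(centers, expected_count=10)
    second = complete_field_grid(first.centers, expected_count=10)
    np.testing.assert_allclose(first.centers, second.centers, atol=1e-9)
    assert second.n_inserted == 0


def test_completion_invariant_to_point_order():
    centers = [(x, 0.0) for x in (0, 10, 20, 30, 50, 60, 70, 80, 90)]
    a = complete_field_grid(centers, 10)
    b = complete_field_grid(centers[::-1], 10)
    np.testing.assert_allclose(a.centers, b.centers, atol=1e-9)


def test_degenerate_and_unreachable_grids_fail():
    with pytest.raises(ValueError):
        complete_field_grid([(5.0, 5.0)] * 4, expected_count=10)
    with pytest.raises(GridCompletionFailure):
        complete_field_grid([(0, 0), (10, 0)], expected_count=10)


def test_consecutive_spacing_invariant():
    centers = [(x, 0.0) for x in (0, 10, 20, 30, 60, 70, 95)]
    grid = complete_field_grid(centers, expected_count=10)
    t = np.sort(grid.centers @ grid.axis)
    gaps = np.diff(t)
    assert ((gaps >= 0.5 * grid.pitch) & (gaps <= 1.5 * grid.pitch)).all()


# ---------------------------------------------------------------------------
# full strip localization
# ---------------------------------------------------------------------------

def _strip_crop(layout, seed, degrade=()):
    cfg = SceneConfig(seed=seed, warp_magnitude=0.05, blur_sigma_px=0.5,
                      noise_sigma=0.01, background="texture",
                      degrade_fields=tuple(degrade))
    scene, gt = render_scene(layout, cfg)
    x, y, w, h = gt.strip_bbox()
    return scene[y:y + h, x:x + w], gt, (x, y)


def _center_in_quad(center, quad):
    # winding test via cross products (quad is convex)
    c = np.asarray(center)
    cross = []
    for i in range(4):
        u = quad[(i + 1) % 4] - quad[i]
        v = c - quad[i]
        cross.append(u[0] * v[1] - u[1] * v[0])
    cross = np.asarray(cross)
    return (cross >= 0).all() or (cross <= 0).all()


def test_clean_strip_yields_correctly_placed_patches(layout):
    crop, gt, (ox, oy) = _strip_crop(layout, seed=41)
    patches = locate_test_fields(crop, layout, seed=0)
    assert [p.parameter for p in patches] == layout.parameter_names
    for p in patches:
        x, y, w, h = p.origin
        center = (ox + x + w / 2, oy + y + h / 2)
        assert _center_in_quad(center, gt.field_rects_scene[p.parameter])


def test_degraded_fields_are_filled_in(layout):
    degrade = ("blood", "protein")
    crop, gt, (ox, oy) = _strip_crop(layout, seed=42, degrade=degrade)
    patches = locate_test_fields(crop, layout, seed=0)
    assert len(patches) == 10
    for p in patches:
        x, y, w, h = p.origin
        center = (ox + x + w / 2, oy + y + h / 2)
        assert _center_in_quad(center, gt.field_rects_scene[p.parameter])


def test_rotated_strip_gives_same_assignment(layout):
    crop, _, _ = _strip_crop(layout, seed=43)
    patches_h = locate_test_fields(crop, layout, seed=0)
    rotated = np.ascontiguousarray(np.rot90(crop, k=3))  # dipped end up
    patches_v = locate_test_fields(rotated, layout, seed=0)
    assert [p.parameter for p in patches_v] == [p.parameter for p in patches_h]
    for ph, pv in zip(patches_h, patches_v):
        mh = ph.pixels.reshape(-1, 3).mean(axis=0)
        mv = pv.pixels.reshape(-1, 3).mean(axis=0)
        assert np.abs(mh - mv).max() < 12  # same pad, slightly shifted crop


def test_featureless_strip_image_raises(layout):
    with pytest.raises(FieldDetectionFailure):
        locate_test_fields(np.full((60, 400, 3), 240, np.uint8), layout)
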