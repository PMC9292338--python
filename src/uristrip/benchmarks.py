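"""Seeded synthetic benchmarks for the three pipeline stages.

Real study photographs are not available, so pipeline quality is measured
on rendered scenes where the ground truth is known exactly: card detection
(success rate and corner error under perspective warp, blur and brightness
shifts), strip field localization (fraction of grid centers placed inside
the true pad rectangles, with some pads' contrast suppressed), and
end-to-end planted-level recovery with per-parameter F1 scores.

Every benchmark derives its per-scene seeds from one master seed and is
fully deterministic.
"""

from __future__ import annotations

import numpy as np

from . import evaluation
from .detect import detect_and_rectify
from .errors import UristripError
from .fields import locate_test_fields
from .layout import StripLayout
from .pipeline import analyze
from .synthgen import SceneConfig, render_card_template, render_scene

_BACKGROUNDS = ("solid", "texture", "photo-like")

#: Degradation level treated as "clean" capture conditions: a hand-held but
#: careful photo — mild perspective, slight defocus, sensor noise.
CLEAN = dict(warp_magnitude=0.05, blur_sigma_px=0.5, brightness_delta=0.0,
             noise_sigma=0.01)


def _quad_contains(quad: np.ndarray, point) -> bool:
    c = np.asarray(point, float)
    cross = []
    for i in range(4):
        u = quad[(i + 1) % 4] - quad[i]
        v = c - quad[i]
        cross.append(u[0] * v[1] - u[1] * v[0])
    cross = np.asarray(cross)
    return bool((cross >= 0).all() or (cross <= 0).all())


def card_detection_benchmark(layout: StripLayout, n: int, seed: int,
                             warp_max: float = 0.15,
                             blur_max: float = 1.5,
                             brightness_max: float = 0.2) -> dict:
    """Detection success rate and mean corner error over ``n`` scenes with
    random warp (up to ``warp_max``), blur and brightness shifts."""
    rng = np.random.default_rng(seed)
    template = render_card_template(layout)
    n_success = 0
    corner_errors = []
    for i in range(n):
        cfg = SceneConfig(
            seed=int(rng.integers(2**31 - 1)),
            warp_magnitude=float(rng.uniform(0, warp_max)),
            blur_sigma_px=float(rng.uniform(0, blur_max)),
            brightness_delta=float(rng.uniform(-brightness_max,
                                               brightness_max)),
            noise_sigma=0.01,
            background=_BACKGROUNDS[i % 3])
        scene, gt = render_scene(layout, cfg)
        try:
            det, _ = detect_and_rectify(scene, template)
        except UristripError:
            continue
        n_success += 1
        corner_errors.append(
            float(np.linalg.norm(det.corners - gt.card_quad, axis=1).mean()))
    return {
        "n": n,
        "success_rate_pct": 100.0 * n_success / n,
        "mean_corner_error_px": float(np.mean(corner_errors))
        if corner_errors else float("nan"),
    }


def field_grid_benchmark(layout: StripLayout, n: int, seed: int,
                         max_degraded: int = 2) -> dict:
    """Fraction of localized pad centers landing inside the true pad
    rectangle, over ``n`` strips with up to ``max_degraded`` washed-out
    pads each."""
    rng = np.random.default_rng(seed)
    n_correct = 0
    n_total = 0
    n_failed = 0
    for i in range(n):
        k = int(rng.integers(0, max_degraded + 1))
        degrade = tuple(rng.choice(layout.parameter_names, size=k,
                                   replace=False)) if k else ()
        cfg = SceneConfig(seed=int(rng.integers(2**31 - 1)),
                          background=_BACKGROUNDS[i % 3],
                          degrade_fields=degrade, **CLEAN)
        scene, gt = render_scene(layout, cfg)
        x, y, w, h = gt.strip_bbox()
        n_total += layout.expected_count
        try:
            patches = locate_test_fields(scene[y:y + h, x:x + w], layout,
                                         seed=cfg.seed)
        except UristripError:
            n_failed += 1
            continue
        for p in patches:
            px, py, pw, ph = p.origin
            center = (x + px + pw / 2, y + py + ph / 2)
            if _quad_contains(gt.field_rects_scene[p.parameter], center):
                n_correct += 1
    return {
        "n": n,
        "n_failed_strips": n_failed,
        "center_accuracy_pct": 100.0 * n_correct / n_total,
    }


def _round_robin_levels(layout: StripLayout, i: int) -> dict[str, str]:
    """Scene ``i`` plants level index i (mod level count) of every
    parameter, so a sweep over scenes covers every level of every pad."""
    return {p.name: p.levels[i % len(p.levels)].label
            for p in layout.parameters}


def end_to_end_benchmark(layout: StripLayout, n: int, seed: int) -> dict:
    """Planted-level recovery and F1 per similarity method on ``n`` clean
    scenes spanning all levels of all parameters."""
    rng = np.random.default_rng(seed)
    methods = ("hue", "matching_factor", "euclidean")
    hits = {m: 0 for m in methods}
    total = n * layout.expected_count
    predictions, manifest = [], []
    for i in range(n):
        cfg = SceneConfig(seed=int(rng.integers(2**31 - 1)),
                          planted_levels=_round_robin_levels(layout, i),
                          background=_BACKGROUNDS[i % 3], **CLEAN)
        scene, gt = render_scene(layout, cfg)
        report = analyze(scene, layout, strip_roi=gt.strip_bbox(),
                         seed=cfg.seed)
        name = f"bench_{i:04d}.png"
        manifest.append({"image": name, "ground_truth": gt.to_dict()})
        doc = report.to_dict()
        doc["image"] = name
        predictions.append(doc)
        if not report.ok:
            continue
        for m in methods:
            hits[m] += sum(r.level.label == gt.planted_levels[r.parameter]
                           for r in report.results[m])
    summary = evaluation.evaluate(predictions, manifest, layout)
    out = {"n": n, "n_decisions": total}
    for m in methods:
        out[f"level_recovery_pct_{m}"] = 100.0 * hits[m] / total
        out[f"macro_f1_{m}"] = summary.macro_f1.get(m, 0.0)
        out[f"pooled_f1_{m}"] = (summary.pooled[m].f1
                                 if m in summary.pooled else 0.0)
    return out
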