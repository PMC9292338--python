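"""End-to-end analysis: detect card, extract colors, match levels, classify.

``analyze`` connects the stages in series: the reference card is located
and rectified by feature matching, its swatches are cropped at constant
coordinates, the strip's pads are localized by the edge/cluster procedure
(on a caller-supplied strip region of interest, or on the whole scene when
none is given — the latter is unreliable and flagged with a warning), and
each pad's histogram-peak color is matched against the parameter's
reference levels under each requested similarity method. Matched levels are
then classified negative/positive.

Strips develop on a schedule: each pad must be read at its manufacturer
read time. ``analyze_session`` accepts one photograph per read time and
takes every parameter's result from the image matching its time; passing a
single image for all times is supported but warned about.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np

from . import colorimetry
from .colorimetry import METHODS, determine_result, hsv_peak
from .detect import DetectedObject, MatchingConfig, detect_and_rectify
from .errors import DetectionFailure, FieldDetectionFailure, GridCompletionFailure
from .fields import PreprocessConfig, extract_reference_fields, locate_test_fields
from .interpret import ParameterResult, classify
from .layout import StripLayout
from .synthgen import render_card_template

Roi = tuple[int, int, int, int]


@dataclass
class AnalysisReport:
    """Per-image outcome: detection diagnostics plus one ParameterResult per
    (parameter, method), or an explicit failure record."""
    image_path: str
    card_detection: Optional[dict] = None
    results: dict[str, list[ParameterResult]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    failure: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.failure is None

    def to_dict(self) -> dict:
        return {
            "image": self.image_path,
            "card_detection": self.card_detection,
            "results": {m: [r.to_dict() for r in rs]
                        for m, rs in self.results.items()},
            "warnings": list(self.warnings),
            "failure": self.failure,
        }


def _load_image(image) -> np.ndarray:
    if isinstance(image, (str, Path)):
        img = iio.imread(image)
    else:
        img = np.asarray(image)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img[..., :3]


def _detection_dict(obj: DetectedObject) -> dict:
    return {"corners": obj.corners.tolist(),
            "n_matches_kept": obj.n_matches_kept,
            "n_inliers": obj.n_inliers}


def analyze(image, layout: StripLayout, *,
            methods: Sequence[str] = METHODS,
            seed: int = 0,
            strip_roi: Optional[Roi] = None,
            matching: Optional[MatchingConfig] = None,
            preprocess: Optional[PreprocessConfig] = None,
            ) -> AnalysisReport:
    """Analyze one photograph containing the strip and its reference card.

    ``strip_roi`` is an (x, y, w, h) scene rectangle containing the strip;
    without it the field finder runs on the full scene, which is documented
    as unreliable. Detection failures are recorded in the report rather
    than raised.
    """
    path = str(image) if isinstance(image, (str, Path)) else "<array>"
    report = AnalysisReport(image_path=path)
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; expected one of {METHODS}")
    scene = _load_image(image)

    template = render_card_template(layout)
    try:
        detection, rectified = detect_and_rectify(scene, template, matching)
    except DetectionFailure as exc:
        report.failure = f"card detection failed: {exc.reason}"
        report.card_detection = {"n_matches_kept": exc.n_matches_kept,
                                 "n_inliers": exc.n_inliers,
                                 "error": exc.reason}
        return report
    report.card_detection = _detection_dict(detection)

    ref_patches = extract_reference_fields(rectified, layout)
    ref_peaks: dict[str, list] = {p.name: [] for p in layout.parameters}
    for patch in ref_patches:
        level = layout.parameter(patch.parameter).level(patch.level)
        ref_peaks[patch.parameter].append((level, hsv_peak(patch)))

    if strip_roi is not None:
        x, y, w, h = strip_roi
        strip_img = scene[y:y + h, x:x + w]
    else:
        strip_img = scene
        report.warnings.append(
            "no strip ROI given; locating fields on the full scene "
            "(unreliable without a strip detector)")
    try:
        test_patches = locate_test_fields(strip_img, layout, seed=seed,
                                          config=preprocess)
    except (FieldDetectionFailure, GridCompletionFailure) as exc:
        report.failure = f"field detection failed: {exc}"
        return report

    test_peaks = {p.parameter: hsv_peak(p) for p in test_patches}
    for method in methods:
        results: list[ParameterResult] = []
        for param in layout.parameters:
            peak = test_peaks[param.name]
            level, score = determine_result(peak, ref_peaks[param.name], method)
            results.append(ParameterResult(
                parameter=param.name, level=level,
                scores={method: score},
                classification=classify(param, level),
                read_time_s=param.read_time_s))
        report.results[method] = results
    return report


def analyze_session(images_by_time: dict[int, object], layout: StripLayout,
                    **kwargs) -> AnalysisReport:
    """Analyze a timed capture session: one image per read time.

    Each parameter's result is taken from the image whose key equals the
    parameter's ``read_time_s``. With a single image supplied for all
    times, every parameter is read from it and a timing warning is
    attached, since pad colors keep developing past their read time.
    """
    if not images_by_time:
        raise ValueError("images_by_time must not be empty")
    single = len(images_by_time) == 1
    reports = {t: analyze(img, layout, **kwargs)
               for t, img in images_by_time.items()}
    merged = AnalysisReport(image_path=";".join(
        r.image_path for r in reports.values()))
    needed = {p.read_time_s for p in layout.parameters}
    if single:
        t0 = next(iter(reports))
        source = {t: t0 for t in needed}
        merged.warnings.append(
            "single-image mode: all parameters read from one photo; "
            "read-time protocol not honored")
    else:
        missing = needed - set(reports)
        if missing:
            raise ValueError(f"no image supplied for read times {sorted(missing)}")
        source = {t: t for t in needed}
    for t, rep in reports.items():
        merged.warnings.extend(rep.warnings)
        if rep.failure:
            merged.failure = rep.failure
            merged.card_detection = rep.card_detection
            return merged
    merged.card_detection = next(iter(reports.values())).card_detection
    for method in next(iter(reports.values())).results:
        results = []
        for param in layout.parameters:
            rep = reports[source[param.read_time_s]]
            results.append(next(r for r in rep.results[method]
                                if r.parameter == param.name))
        merged.results[method] = results
    return merged


def write_report(report: AnalysisReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
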