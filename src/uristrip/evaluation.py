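"""Evaluation harness: per-parameter confusion matrices and F1 scores.

Predictions (analysis reports) are joined to a ground-truth manifest by
image id; for every parameter and similarity method, the negative/positive
classification is compared with the classification of the planted level,
yielding binary confusion counts, precision, recall and F1 (with the
0/0 -> 0 convention). F1 is aggregated two ways, since either can be
meant by an "average" score: macro (mean of per-parameter F1) and pooled
(one F1 over all decisions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .interpret import POSITIVE, classify
from .layout import StripLayout


@dataclass
class ConfusionCell:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def add(self, predicted_positive: bool, truth_positive: bool) -> None:
        if truth_positive:
            if predicted_positive:
                self.tp += 1
            else:
                self.fn += 1
        else:
            if predicted_positive:
                self.fp += 1
            else:
                self.tn += 1

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1}


@dataclass
class EvaluationSummary:
    """Confusion counts and F1 per (method, parameter), plus aggregates."""
    cells: dict[str, dict[str, ConfusionCell]]   # method -> parameter -> cell
    macro_f1: dict[str, float]
    pooled: dict[str, ConfusionCell]
    n_images: int

    def to_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "per_parameter": {m: {p: c.to_dict() for p, c in cells.items()}
                              for m, cells in self.cells.items()},
            "macro_f1": dict(self.macro_f1),
            "pooled_f1": {m: c.f1 for m, c in self.pooled.items()},
            "pooled": {m: c.to_dict() for m, c in self.pooled.items()},
        }


def _image_id(path: str) -> str:
    return path.replace("\\", "/").rsplit("/", 1)[-1]


def evaluate(predictions: list[dict], manifest: list[dict],
             layout: StripLayout) -> EvaluationSummary:
    """Score analysis reports against a ground-truth manifest.

    ``predictions`` are report dicts (``AnalysisReport.to_dict``);
    ``manifest`` records come from the scene generator. Reports that carry
    a failure are skipped (they contribute no decisions). Raises
    ``KeyError`` listing any prediction whose image id has no truth record.
    """
    truth_by_id = {_image_id(rec["image"]): rec for rec in manifest}
    unmatched = [p["image"] for p in predictions
                 if _image_id(p["image"]) not in truth_by_id]
    if unmatched:
        raise KeyError(f"predictions without a truth record: {unmatched}")

    cells: dict[str, dict[str, ConfusionCell]] = {}
    pooled: dict[str, ConfusionCell] = {}
    n_images = 0
    for pred in sorted(predictions, key=lambda p: _image_id(p["image"])):
        if pred.get("failure"):
            continue
        n_images += 1
        truth = truth_by_id[_image_id(pred["image"])]
        planted = truth["ground_truth"]["planted_levels"]
        for method, results in pred["results"].items():
            mcells = cells.setdefault(method, {})
            pcell = pooled.setdefault(method, ConfusionCell())
            for r in results:
                param = layout.parameter(r["parameter"])
                true_level = param.level(planted[param.name])
                truth_pos = classify(param, true_level) == POSITIVE
                pred_pos = r["classification"] == POSITIVE
                cell = mcells.setdefault(param.name, ConfusionCell())
                cell.add(pred_pos, truth_pos)
                pcell.add(pred_pos, truth_pos)

    macro = {m: (sum(c.f1 for c in mc.values()) / len(mc) if mc else 0.0)
             for m, mc in cells.items()}
    return EvaluationSummary(cells=cells, macro_f1=macro, pooled=pooled,
                             n_images=n_images)
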