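"""Clinical interpretation: negative/positive rules and the read schedule.

Most pads are read against a detection limit: in healthy urine glucose,
bilirubin, ketone, blood, protein, nitrite and leukocytes sit below the
strip's detection limit, so the matched level is negative exactly when it
is the lowest level of that parameter. Three parameters are value-based:

* pH is pathological (positive) strictly above 7.0;
* specific gravity is negative within the inclusive band
  1.005-1.025 g/ml, positive outside it;
* urobilinogen is negative strictly below 1 mg/dl.

Each pad also has a manufacturer read time (30-120 s after dipping); the
schedule groups parameters by that time so a capture workflow knows when to
photograph which pads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .layout import Level, Parameter, StripLayout
from .colorimetry import SimilarityScore

NEGATIVE = "negative"
POSITIVE = "positive"

#: Parameters whose classification depends on the level's numeric value.
_VALUE_RULES = ("ph", "specific_gravity", "urobilinogen")


@dataclass(frozen=True)
class ParameterResult:
    """Outcome for one pad under one similarity method."""
    parameter: str
    level: Level
    scores: dict[str, SimilarityScore]
    classification: str          # "negative" | "positive"
    read_time_s: int

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "level": self.level.label,
            "value": self.level.value,
            "unit": self.level.unit,
            "scores": {m: s.value for m, s in self.scores.items()},
            "classification": self.classification,
            "read_time_s": self.read_time_s,
        }


def classify(parameter: Parameter, level: Level) -> str:
    """Binary classification of a matched level.

    Pure function of (parameter, level). Value-based parameters require a
    numeric level value and raise ``ValueError`` without one; all other
    parameters use the detection-limit rule (negative iff lowest level).
    """
    name = parameter.name.lower()
    if name in _VALUE_RULES:
        if level.value is None:
            raise ValueError(
                f"parameter {parameter.name!r} needs a numeric level value "
                f"to classify, got level {level.label!r} with value None")
        v = level.value
        if name == "ph":
            return POSITIVE if v > 7.0 else NEGATIVE
        if name == "specific_gravity":
            return NEGATIVE if 1.005 <= v <= 1.025 else POSITIVE
        return NEGATIVE if v < 1.0 else POSITIVE  # urobilinogen, mg/dl
    # detection-limit rule
    return NEGATIVE if level.label == parameter.levels[0].label else POSITIVE


def read_schedule(layout: StripLayout) -> list[tuple[int, list[str]]]:
    """Group parameter names by read time, ordered by time ascending."""
    groups: dict[int, list[str]] = {}
    for p in layout.parameters:
        groups.setdefault(p.read_time_s, []).append(p.name)
    return sorted(groups.items())
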