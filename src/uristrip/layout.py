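"""Declarative description of a urine test strip and its reference card.

A :class:`StripLayout` tells every other module what to expect: the ten
analyte parameters in their physical order along the strip (starting from
the dipped end), the graded levels of each parameter with their semantic
values, the manufacturer read time of each pad, and where each reference
swatch sits on the canonical reference card.

Conventions used throughout the package (stated once, here):

* coordinates are 0-based pixel units,
* rectangles are ``(x, y, width, height)``,
* y increases downward.

The reference card's swatch coordinates and level values are configuration,
not code: the shipped default layout uses schematic colors and plausible
level values, and any clinical deployment must substitute the values of the
actual strip manufacturer. Layout documents are accepted as JSON or YAML and
validated against the published JSON Schema (see :func:`layout_schema`).
"""

from __future__ import annotations

import colorsys
import json
from importlib import resources
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import LayoutError

#: Read times (seconds after dipping) supported by the workflow.
ALLOWED_READ_TIMES = (30, 40, 45, 60, 120)

Rect = tuple[int, int, int, int]
Rgb = tuple[int, int, int]


class Level(BaseModel):
    """One graded outcome of an analyte pad.

    ``value``/``unit`` carry the semantic concentration (``None`` for purely
    categorical levels such as a nitrite "negative"); ``color_rgb`` is the
    sRGB color of the corresponding reference swatch, used to render the
    canonical card and strip templates.
    """

    model_config = ConfigDict(frozen=True)

    label: str
    value: Optional[float] = None
    unit: Optional[str] = None
    color_rgb: Rgb

    @model_validator(mode="after")
    def _check_rgb(self) -> "Level":
        if not all(0 <= c <= 255 for c in self.color_rgb):
            raise ValueError(f"color_rgb out of range for level {self.label!r}")
        return self


class Parameter(BaseModel):
    """A single analyte: its name, read time and ordered levels."""

    model_config = ConfigDict(frozen=True)

    name: str
    read_time_s: int
    levels: tuple[Level, ...] = Field(min_length=1)

    @model_validator(mode="after")
    def _check(self) -> "Parameter":
        if self.read_time_s not in ALLOWED_READ_TIMES:
            raise ValueError(
                f"read_time_s={self.read_time_s} for {self.name!r} "
                f"not in {ALLOWED_READ_TIMES}")
        labels = [lv.label for lv in self.levels]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate level labels in parameter {self.name!r}")
        return self

    def level(self, label: str) -> Level:
        for lv in self.levels:
            if lv.label == label:
                return lv
        raise KeyError(f"parameter {self.name!r} has no level {label!r}")


class StripLayout(BaseModel):
    """Full geometric and semantic description of strip + reference card.

    ``parameters`` are in physical order along the strip from the dipped
    end. ``card_coords`` maps parameter name -> level label -> swatch
    rectangle in the canonical card frame of size ``card_size``.
    """

    model_config = ConfigDict(frozen=True)

    parameters: tuple[Parameter, ...] = Field(min_length=1)
    field_side: int
    field_pitch: int
    card_size: tuple[int, int]
    strip_size: tuple[int, int]
    card_coords: dict[str, dict[str, Rect]]

    @model_validator(mode="after")
    def _check(self) -> "StripLayout":
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        if not (self.field_pitch >= self.field_side > 0):
            raise ValueError("field_pitch >= field_side > 0 required")
        cw, ch = self.card_size
        for p in self.parameters:
            rects = self.card_coords.get(p.name)
            if rects is None:
                raise ValueError(f"card_coords missing parameter {p.name!r}")
            for lv in p.levels:
                rect = rects.get(lv.label)
                if rect is None:
                    raise ValueError(
                        f"card_coords missing rectangle for "
                        f"({p.name!r}, {lv.label!r})")
                x, y, w, h = rect
                if w <= 0 or h <= 0 or x < 0 or y < 0 or x + w > cw or y + h > ch:
                    raise ValueError(
                        f"card rectangle for ({p.name!r}, {lv.label!r}) "
                        f"outside card_size {self.card_size}")
        return self

    # -- convenience accessors ------------------------------------------------

    @property
    def parameter_names(self) -> list[str]:
        return [p.name for p in self.parameters]

    @property
    def expected_count(self) -> int:
        """Number of test fields a strip of this layout carries."""
        return len(self.parameters)

    def parameter(self, name: str) -> Parameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(f"no parameter named {name!r}")

    def card_rect(self, parameter: str, level: str) -> Rect:
        return self.card_coords[parameter][level]

    def to_document(self) -> dict:
        """Plain-dict form suitable for JSON/YAML serialization."""
        return json.loads(self.model_dump_json())


def load_layout(source) -> StripLayout:
    """Load and validate a layout from a path, text, or parsed document.

    Accepts a filesystem path to a ``.json``/``.yaml`` file, a JSON/YAML
    string, or an already-parsed mapping. Raises :class:`LayoutError` with
    the offending path on any schema or invariant violation.
    """
    if isinstance(source, dict):
        doc = source
    else:
        text = source
        try:
            from pathlib import Path
            p = Path(source)
            if p.exists() and p.is_file():
                text = p.read_text()
        except OSError:
            pass
        doc = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(doc, dict):
        raise LayoutError("layout document is not a mapping")
    try:
        return StripLayout.model_validate(doc)
    except ValidationError as exc:
        locs = "; ".join(
            "/".join(str(x) for x in err["loc"]) + ": " + err["msg"]
            for err in exc.errors())
        raise LayoutError(f"invalid layout: {locs}") from exc


def layout_schema() -> dict:
    """JSON Schema for layout documents."""
    return StripLayout.model_json_schema()


# ---------------------------------------------------------------------------
# Default Multistix-style 10-parameter layout
# ---------------------------------------------------------------------------

def _hsv255(h_deg: float, s: float, v: float) -> Rgb:
    r, g, b = colorsys.hsv_to_rgb((h_deg % 360.0) / 360.0, s, v)
    return (round(r * 255), round(g * 255), round(b * 255))


def _ramp(labels_values, unit, h0, h_step, s0=0.55, s1=0.85, v0=0.90, v1=0.72):
    n = len(labels_values)
    out = []
    for i, (label, value) in enumerate(labels_values):
        t = i / max(n - 1, 1)
        out.append(Level(
            label=label, value=value, unit=unit,
            color_rgb=_hsv255(h0 + i * h_step, s0 + t * (s1 - s0),
                              v0 + t * (v1 - v0))))
    return tuple(out)


def _default_parameters() -> tuple[Parameter, ...]:
    # Hue ramps are schematic: monotone in hue so each graded level is
    # colorimetrically distinct, loosely evoking the real pad chemistry.
    glucose = _ramp([("negative", None), ("100", 100.0), ("250", 250.0),
                     ("500", 500.0), ("1000", 1000.0), ("2000", 2000.0)],
                    "mg/dl", 200, -35)
    bilirubin = _ramp([("negative", None), ("small", 0.5),
                       ("moderate", 1.0), ("large", 3.0)], "mg/dl", 55, 80)
    ketone = _ramp([("negative", None), ("trace", 5.0), ("small", 15.0),
                    ("moderate", 40.0), ("large", 80.0), ("very_large", 160.0)],
                   "mg/dl", 45, -30)
    sg = _ramp([("1.000", 1.000), ("1.005", 1.005), ("1.010", 1.010),
                ("1.015", 1.015), ("1.020", 1.020), ("1.025", 1.025),
                ("1.030", 1.030)], "g/ml", 230, -30)
    blood = _ramp([("negative", None), ("trace", 10.0), ("small", 25.0),
                   ("moderate", 80.0), ("large", 200.0)], "Ery/ul", 60, 20)
    ph = _ramp([("5.0", 5.0), ("6.0", 6.0), ("6.5", 6.5), ("7.0", 7.0),
                ("7.5", 7.5), ("8.0", 8.0), ("8.5", 8.5)], "pH", 20, 30)
    protein = _ramp([("negative", None), ("trace", 15.0), ("30", 30.0),
                     ("100", 100.0), ("300", 300.0), ("2000", 2000.0)],
                    "mg/dl", 70, 20)
    urobilinogen = _ramp([("0.2", 0.2), ("1", 1.0), ("2", 2.0),
                          ("4", 4.0), ("8", 8.0)], "mg/dl", 350, -16)
    nitrite = (
        Level(label="negative", value=None, unit=None,
              color_rgb=_hsv255(0, 0.04, 0.96)),
        Level(label="positive", value=None, unit=None,
              color_rgb=_hsv255(340, 0.60, 0.88)),
    )
    leukocytes = _ramp([("negative", None), ("trace", 15.0), ("small", 70.0),
                        ("moderate", 125.0), ("large", 500.0)], "Leu/ul", 55, -40)
    return (
        Parameter(name="glucose", read_time_s=30, levels=glucose),
        Parameter(name="bilirubin", read_time_s=30, levels=bilirubin),
        Parameter(name="ketone", read_time_s=40, levels=ketone),
        Parameter(name="specific_gravity", read_time_s=45, levels=sg),
        Parameter(name="blood", read_time_s=60, levels=blood),
        Parameter(name="ph", read_time_s=60, levels=ph),
        Parameter(name="protein", read_time_s=60, levels=protein),
        Parameter(name="urobilinogen", read_time_s=60, levels=urobilinogen),
        Parameter(name="nitrite", read_time_s=60, levels=nitrite),
        Parameter(name="leukocytes", read_time_s=120, levels=leukocytes),
    )


# canonical card geometry (pixels in the canonical card frame)
_CARD_LABEL_W = 40     # left band reserved for row labels / fiducial texture
_CARD_TOP = 18
_SWATCH_W, _SWATCH_H = 22, 14
_PITCH_X, _PITCH_Y = 26, 24


def default_layout() -> StripLayout:
    """The shipped Multistix-style layout: 10 parameters, 5 read-time groups.

    Physical order from the dipped end follows the common arrangement of
    off-the-shelf 10-pad strips; it is an assumption of this default file,
    not a property of the method, and is overridden by editing the layout.
    """
    params = _default_parameters()
    coords: dict[str, dict[str, Rect]] = {}
    for r, p in enumerate(params):
        row: dict[str, Rect] = {}
        for i, lv in enumerate(p.levels):
            row[lv.label] = (_CARD_LABEL_W + 4 + i * _PITCH_X,
                             _CARD_TOP + r * _PITCH_Y, _SWATCH_W, _SWATCH_H)
        coords[p.name] = row
    card_w = _CARD_LABEL_W + 4 + 7 * _PITCH_X + 4     # 230
    card_h = _CARD_TOP + len(params) * _PITCH_Y + 4   # 262
    return StripLayout(
        parameters=params,
        field_side=40,
        field_pitch=56,
        card_size=(card_w, card_h),
        strip_size=(560, 64),
        card_coords=coords,
    )


def shipped_layout_path() -> str:
    """Path of the packaged default layout JSON file."""
    return str(resources.files("uristrip").joinpath("data/default_layout.json"))
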