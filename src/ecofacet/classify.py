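"""Deterministic classifiers onto the categorical scales.

Boundary conventions (fixed here because the source ranges are printed
without inclusivity):

* spatial scale classes: lower bound inclusive, upper bound exclusive —
  an area exactly on a boundary belongs to the upper class;
* geological boundaries: an age exactly on a boundary belongs to the
  *younger* unit;
* time-unit classification: floor rule — the largest unit whose span is
  less than or equal to the interval.

All numeric boundaries are data, read from the packaged vocabulary tables
(``lower_m2``/``upper_m2`` on spatial classes, ``seconds`` on time units,
``start_ma``/``end_ma`` on chronostratigraphic units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ClassificationError
from .vocabulary import Term, Vocabulary, load_vocabulary

__all__ = [
    "ScaleClass",
    "scale_classes",
    "classify_spatial_scale",
    "classify_time_unit",
    "geological_context",
    "bbox_contains",
    "GEOLOGICAL_RANKS",
]

GEOLOGICAL_RANKS = ("eon", "era", "period", "epoch", "age")

#: exact unit conversion factors to square metres
AREA_UNITS = {"m2": 1.0, "km2": 1e6, "ha": 1e4}


@dataclass(frozen=True)
class ScaleClass:
    label: str
    lower_m2: float          # inclusive
    upper_m2: float | None   # exclusive; None for the topmost class
    order: int

    def contains(self, area_m2: float) -> bool:
        if area_m2 < self.lower_m2:
            return False
        return self.upper_m2 is None or area_m2 < self.upper_m2


def _default_vocab(vocab: Vocabulary | None) -> Vocabulary:
    global _PACKAGED
    if vocab is not None:
        return vocab
    if _PACKAGED is None:
        _PACKAGED = load_vocabulary()
    return _PACKAGED


_PACKAGED: Vocabulary | None = None


def scale_classes(vocab: Vocabulary | None = None) -> list[ScaleClass]:
    """The ordered spatial scale classes with their areal bounds in m²."""
    vocab = _default_vocab(vocab)
    out = []
    for i, t in enumerate(vocab.terms_at("space/resolution")):
        lower = t.extra_float("lower_m2")
        upper = t.extra_float("upper_m2")
        if lower is None:
            raise ClassificationError(
                f"scale class {t.label!r} lacks a lower_m2 bound")
        out.append(ScaleClass(t.label, lower, upper, i))
    return out


def classify_spatial_scale(area: float, unit: str = "m2",
                           vocab: Vocabulary | None = None) -> str:
    """Map an area onto a scale class label (Point/Plot/Region/...)."""
    try:
        factor = AREA_UNITS[unit]
    except KeyError:
        raise ClassificationError(
            f"unknown area unit {unit!r}; use one of {sorted(AREA_UNITS)}")
    if not (isinstance(area, (int, float)) and math.isfinite(area)) or area <= 0:
        raise ClassificationError(f"area must be positive and finite, got {area!r}")
    area_m2 = float(area) * factor
    for cls in scale_classes(vocab):
        if cls.contains(area_m2):
            return cls.label
    raise ClassificationError(
        f"scale class table does not cover area {area_m2} m2")


def classify_time_unit(interval_seconds: float,
                       vocab: Vocabulary | None = None) -> str:
    """Largest time-unit class whose span is <= the interval (floor rule)."""
    if not math.isfinite(interval_seconds) or interval_seconds <= 0:
        raise ClassificationError(
            f"interval must be positive and finite, got {interval_seconds!r}")
    vocab = _default_vocab(vocab)
    units = [(t.extra_float("seconds"), t.label)
             for t in vocab.terms_at("time/unit")]
    units = [(s, lbl) for s, lbl in units if s is not None]
    fitting = [(s, lbl) for s, lbl in units if s <= interval_seconds]
    if not fitting:
        # shorter than the smallest unit: classify as the smallest
        return min(units)[1]
    return max(fitting)[1]


def geological_context(age_ma: float,
                       vocab: Vocabulary | None = None) -> list[Term]:
    """Chronostratigraphic chain (eon first, then each finer applicable
    rank) for an age in millions of years before present.

    An age exactly on a packaged boundary is assigned to the younger unit.
    Units without numeric bounds in the table (informal groupings) are
    never assigned.
    """
    if not math.isfinite(age_ma) or age_ma < 0:
        raise ClassificationError(f"age must be >= 0 and finite, got {age_ma!r}")
    vocab = _default_vocab(vocab)
    chain: list[Term] = []
    for rank in GEOLOGICAL_RANKS:
        best = None
        for t in vocab.terms_at(f"time/geological/{rank}"):
            start, end = t.extra_float("start_ma"), t.extra_float("end_ma")
            if start is None or end is None:
                continue
            if start <= age_ma <= end:
                if best is None or start < best.extra_float("start_ma"):
                    best = t  # boundary tie: keep the younger unit
        if best is None:
            break
        if chain and best.parent_id != chain[-1].id:
            break  # defensive: never extend an inconsistent chain
        chain.append(best)
    if not chain:
        raise ClassificationError(
            f"age {age_ma} Ma is beyond the packaged chart span")
    return chain


def bbox_contains(box, latitude: float, longitude: float) -> bool:
    """Inclusive containment test for a decimal-degree bounding box.

    ``box`` is anything with west/south/east/north attributes or a
    (west, south, east, north) sequence.  Boxes with west > east wrap
    across the antimeridian.
    """
    if hasattr(box, "west"):
        west, south, east, north = box.west, box.south, box.east, box.north
    else:
        west, south, east, north = box
    if not (-90.0 <= latitude <= 90.0):
        raise ClassificationError(f"latitude {latitude} out of range")
    if not (-180.0 <= longitude <= 180.0):
        raise ClassificationError(f"longitude {longitude} out of range")
    if not (south <= latitude <= north):
        return False
    if west <= east:
        return west <= longitude <= east
    return longitude >= west or longitude <= east
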