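"""Reference-anchored nutrient concentration classes.

Rather than comparing vegetable composition to daily requirements (which
depend on bioavailability and demographics), concentrations are benchmarked
against a reference set of widely grown and marketed vegetable crops. For
each nutrient the reference range [ref_min, ref_max] is split into equal
thirds — *low*, *medium*, *high* — while values below the reference minimum
are *very low*, values above the reference maximum up to twice the maximum
are *very high*, and values beyond twice the maximum are *extremely high*.
A nutrient at very-high or extremely-high level is called *superabundant*.

All boundaries are kept at full precision; two-decimal rounding is applied
only when rendering a bounds table for display.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Nutrient",
    "NUTRIENT_UNITS",
    "ConcentrationClass",
    "ReferenceSet",
    "ClassBounds",
    "InsufficientReferenceError",
    "DegenerateRangeError",
    "derive_class_bounds",
    "derive_all_bounds",
    "classify",
    "is_superabundant",
    "load_reference_csv",
]


class Nutrient(str, enum.Enum):
    """The nine nutrients assessed: dietary fiber, four minerals, and four
    vitamins (iodine is excluded — terrestrial plants carry no useful
    amount)."""

    fiber = "fiber"
    Ca = "Ca"
    Fe = "Fe"
    Mg = "Mg"
    Zn = "Zn"
    vitA = "vitA"
    folate = "folate"
    vitC = "vitC"
    vitE = "vitE"


#: Units per 100 g fresh weight.
NUTRIENT_UNITS: dict[Nutrient, str] = {
    Nutrient.fiber: "g/100g",
    Nutrient.Ca: "mg/100g",
    Nutrient.Fe: "mg/100g",
    Nutrient.Mg: "mg/100g",
    Nutrient.Zn: "mg/100g",
    Nutrient.vitA: "mg RAE/100g",
    Nutrient.folate: "mcg/100g",
    Nutrient.vitC: "mg/100g",
    Nutrient.vitE: "mg/100g",
}


class ConcentrationClass(enum.IntEnum):
    """Ordered six-class scale; comparison follows concentration order."""

    very_low = 0
    low = 1
    medium = 2
    high = 3
    very_high = 4
    extremely_high = 5

    @property
    def label(self) -> str:
        return _CLASS_LABELS[self]


_CLASS_LABELS = {
    ConcentrationClass.very_low: "VL",
    ConcentrationClass.low: "L",
    ConcentrationClass.medium: "M",
    ConcentrationClass.high: "H",
    ConcentrationClass.very_high: "VH",
    ConcentrationClass.extremely_high: "XH",
}

#: Short display labels (as used in published multi-nutrient tables) -> class.
CLASS_FROM_LABEL = {v: k for k, v in _CLASS_LABELS.items()}


class InsufficientReferenceError(ValueError):
    """Fewer than two reference crops report the nutrient."""


class DegenerateRangeError(ValueError):
    """All reference values identical; tertiles are undefined."""


@dataclass(frozen=True)
class ReferenceSet:
    """Reference crops with their per-nutrient concentrations.

    ``crops`` maps crop name -> {nutrient: concentration}; missing nutrients
    are simply absent from a crop's mapping and are excluded from range
    computation. An outlier crop (e.g. cassava leaf, whose leaf values dwarf
    the rest of the set) may be dropped at construction.
    """

    crops: Mapping[str, Mapping[Nutrient, float]]

    def values_for(self, nutrient: Nutrient) -> list[float]:
        return [
            profile[nutrient]
            for profile in self.crops.values()
            if nutrient in profile
        ]

    def range_for(self, nutrient: Nutrient) -> tuple[float, float]:
        vals = self.values_for(nutrient)
        if len(vals) < 2:
            raise InsufficientReferenceError(
                f"need >= 2 reference values for {nutrient.value}, got {len(vals)}"
            )
        return min(vals), max(vals)


@dataclass(frozen=True)
class ClassBounds:
    """Class boundaries for one nutrient, derived from a reference range.

    ``t1`` and ``t2`` are the interior tertile edges of [ref_min, ref_max];
    ``vh_upper`` is always twice ``ref_max`` (the very-high/extremely-high
    boundary). When ``ref_min`` is 0 the very-low class cannot exist and
    ``has_very_low`` is False.
    """

    nutrient: Nutrient
    ref_min: float
    ref_max: float

    def __post_init__(self) -> None:
        if not (0 <= self.ref_min <= self.ref_max) or not math.isfinite(self.ref_max):
            raise ValueError("require 0 <= ref_min <= ref_max, finite")
        if self.ref_min == self.ref_max:
            raise DegenerateRangeError(
                f"degenerate reference range for {self.nutrient.value}"
            )

    @property
    def t1(self) -> float:
        return self.ref_min + (self.ref_max - self.ref_min) / 3.0

    @property
    def t2(self) -> float:
        return self.ref_min + 2.0 * (self.ref_max - self.ref_min) / 3.0

    @property
    def vh_upper(self) -> float:
        return 2.0 * self.ref_max

    @property
    def has_very_low(self) -> bool:
        return self.ref_min > 0.0


def derive_class_bounds(reference: ReferenceSet, nutrient: Nutrient) -> ClassBounds:
    """Derive class boundaries for one nutrient from a reference set."""
    ref_min, ref_max = reference.range_for(nutrient)
    return ClassBounds(nutrient=nutrient, ref_min=ref_min, ref_max=ref_max)


def derive_all_bounds(reference: ReferenceSet) -> dict[Nutrient, ClassBounds]:
    """Boundaries for every nutrient with at least two reference values."""
    out: dict[Nutrient, ClassBounds] = {}
    for nutrient in Nutrient:
        try:
            out[nutrient] = derive_class_bounds(reference, nutrient)
        except InsufficientReferenceError:
            continue
    return out


def classify(value: float, bounds: ClassBounds) -> ConcentrationClass:
    """Assign a concentration (per 100 g fresh weight) to its class.

    Intervals are half-open on the upper side within the reference range and
    closed at ``ref_max``: [0, ref_min) very-low, [ref_min, t1) low,
    [t1, t2) medium, [t2, ref_max] high, (ref_max, 2*ref_max] very-high,
    (2*ref_max, inf) extremely-high. Without a very-low class, [0, t1) is low.
    """
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"concentration must be finite and >= 0, got {value!r}")
    if bounds.has_very_low and value < bounds.ref_min:
        return ConcentrationClass.very_low
    if value < bounds.t1:
        return ConcentrationClass.low
    if value < bounds.t2:
        return ConcentrationClass.medium
    if value <= bounds.ref_max:
        return ConcentrationClass.high
    if value <= bounds.vh_upper:
        return ConcentrationClass.very_high
    return ConcentrationClass.extremely_high


def is_superabundant(cls: ConcentrationClass) -> bool:
    """True for very-high or extremely-high — above the reference maximum."""
    return cls >= ConcentrationClass.very_high


def load_reference_csv(
    path: str | Path, *, exclude: Iterable[str] = ()
) -> ReferenceSet:
    """Read a reference-crop CSV (``crop_name`` + one column per nutrient
    code; empty cell = missing). Crops named in ``exclude`` are dropped."""
    df = pd.read_csv(path)
    if "crop_name" not in df.columns:
        raise ValueError("reference CSV must have a crop_name column")
    dropped = set(exclude)
    crops: dict[str, dict[Nutrient, float]] = {}
    for _, row in df.iterrows():
        name = str(row["crop_name"])
        if name in dropped:
            continue
        profile: dict[Nutrient, float] = {}
        for nutrient in Nutrient:
            if nutrient.value in df.columns and pd.notna(row[nutrient.value]):
                profile[nutrient] = float(row[nutrient.value])
        crops[name] = profile
    return ReferenceSet(crops=crops)
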