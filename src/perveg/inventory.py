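"""Cultivated perennial-vegetable (PV) species inventory: records, I/O, breakdowns.

A perennial vegetable is a crop living three or more years whose vegetative
or reproductive structures are eaten as a vegetable and that yields more than
one year of harvest. Each cultivated species is described by a set of
categorical traits — growth form, plant parts eaten, thermal-climate and
moisture adaptation, shade tolerance, domestication status and lifecycle —
and the module summarises a species table into the category breakdowns used
in biodiversity reporting (form shares, part-used shares with multi-counting,
climate roll-ups, domestication shares) plus a few pieces of cultivated-area
arithmetic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from ._util import round_half_up

__all__ = [
    "Form",
    "Part",
    "ThermalClimate",
    "Moisture",
    "Shade",
    "Domestication",
    "Lifecycle",
    "SpeciesRecord",
    "CategoryBreakdown",
    "AreaComponent",
    "SpeciesTableError",
    "load_species_table",
    "write_species_table",
    "breakdown",
    "perennial_share",
    "domestication_share",
    "current_area",
    "CLIMATE_ROLLUP",
]


class Form(str, enum.Enum):
    """Growth form. Trees, shrubs, bamboos, palms, cacti and woody
    succulents are all encoded as ``woody``; lianas and herbaceous climbers
    as ``vine``; forbs, ferns, grasses and aquatics as ``herb``."""

    woody = "woody"
    vine = "vine"
    herb = "herb"


class Part(str, enum.Enum):
    leaf = "leaf"
    shoot = "shoot"
    other_vegetative = "other_vegetative"
    flowerbud = "flowerbud"
    flower = "flower"
    unripe_fruit = "unripe_fruit"
    ripe_fruit = "ripe_fruit"
    unripe_seed = "unripe_seed"
    stem = "stem"


class ThermalClimate(str, enum.Enum):
    tropical_lowland = "tropical_lowland"
    tropical_highland = "tropical_highland"
    subtropical = "subtropical"
    warm_temperate = "warm_temperate"
    cold_temperate = "cold_temperate"
    boreal = "boreal"
    arctic = "arctic"


class Moisture(str, enum.Enum):
    humid = "humid"
    semi_arid = "semi_arid"
    arid = "arid"
    aquatic = "aquatic"


class Shade(str, enum.Enum):
    full_shade = "full_shade"
    partial_shade = "partial_shade"
    sun_only = "sun_only"


class Domestication(str, enum.Enum):
    """Market status: global (> $1B sales, multi-region), minor global
    (multi-region, < $1B), regional (never left region of origin), historic
    (abandoned), new/experimental (under development)."""

    global_ = "global"
    minor_global = "minor_global"
    regional = "regional"
    historic = "historic"
    new_experimental = "new_experimental"


class Lifecycle(str, enum.Enum):
    perennial = "perennial"
    perennial_grown_as_annual = "perennial_grown_as_annual"


#: Reporting roll-up of the seven thermal climates into three broad bands.
CLIMATE_ROLLUP: dict[str, frozenset[ThermalClimate]] = {
    "tropical": frozenset(
        {
            ThermalClimate.tropical_lowland,
            ThermalClimate.tropical_highland,
            ThermalClimate.subtropical,
        }
    ),
    "temperate": frozenset(
        {ThermalClimate.warm_temperate, ThermalClimate.cold_temperate}
    ),
    "boreal_arctic": frozenset({ThermalClimate.boreal, ThermalClimate.arctic}),
}


class SpeciesTableError(ValueError):
    """Schema or validation failure in a species table."""


class SpeciesRecord(BaseModel):
    """One cultivated PV species and its categorical traits."""

    model_config = ConfigDict(frozen=True)

    species_name: str
    family: str
    form: Form
    parts: frozenset[Part]
    thermal_climates: frozenset[ThermalClimate]
    moisture: frozenset[Moisture]
    shade: Shade
    domestication: Domestication
    lifecycle: Lifecycle = Lifecycle.perennial

    @field_validator("parts", "thermal_climates", "moisture")
    @classmethod
    def _non_empty(cls, v: frozenset) -> frozenset:
        if not v:
            raise ValueError("set-valued trait must be non-empty")
        return v


@dataclass(frozen=True)
class CategoryBreakdown:
    """Counts and percentage shares of a categorical trait over a table.

    For set-valued traits (parts, climates, moisture) a species contributes
    once per value it carries and ``multi_counted`` is True; the percentage
    denominator is then the number of (species, value) pairs unless
    ``denominator`` was fixed to the species count.
    """

    category_field: str
    counts: dict[str, int]
    denominator: int
    multi_counted: bool = False

    @property
    def percentages(self) -> dict[str, float]:
        if self.denominator == 0:
            return {k: 0.0 for k in self.counts}
        return {k: 100.0 * v / self.denominator for k, v in self.counts.items()}

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        return {k: round_half_up(v, ndigits) for k, v in self.percentages.items()}


@dataclass(frozen=True)
class AreaComponent:
    """One crop's contribution to current PV cultivated area.

    ``vegetable_use_fraction`` covers dual-use crops: e.g. only the share of
    the olive area grown for table olives counts as vegetable land.
    """

    crop: str
    production_area_Mha: float
    vegetable_use_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.production_area_Mha < 0:
            raise SpeciesTableError(f"negative area for {self.crop!r}")
        if not 0.0 <= self.vegetable_use_fraction <= 1.0:
            raise SpeciesTableError(
                f"vegetable_use_fraction outside [0, 1] for {self.crop!r}"
            )

    @property
    def vegetable_area_Mha(self) -> float:
        return self.production_area_Mha * self.vegetable_use_fraction


_REQUIRED_COLUMNS = [
    "species_name",
    "family",
    "form",
    "parts",
    "thermal_climates",
    "moisture",
    "shade",
    "domestication",
    "lifecycle",
]
_SET_COLUMNS = {"parts", "thermal_climates", "moisture"}

#: Delimiter separating multiple values inside one CSV cell.
SET_DELIMITER = ";"


def load_species_table(
    path: str | Path, *, delimiter: str = ",", set_delimiter: str = SET_DELIMITER
) -> list[SpeciesRecord]:
    """Read a species CSV into validated records, preserving row order.

    Set-valued cells (parts, thermal_climates, moisture) hold
    ``set_delimiter``-separated tokens. Raises :class:`SpeciesTableError`
    naming the offending column or row on any schema or validation problem,
    including duplicated species names.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SpeciesTableError(f"missing required column(s): {', '.join(missing)}")

    records: list[SpeciesRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        kwargs: dict = {}
        for col in _REQUIRED_COLUMNS:
            raw = getattr(row, col).strip()
            if col in _SET_COLUMNS:
                kwargs[col] = frozenset(
                    t.strip() for t in raw.split(set_delimiter) if t.strip()
                )
            else:
                kwargs[col] = raw
        try:
            rec = SpeciesRecord(**kwargs)
        except Exception as exc:
            raise SpeciesTableError(f"row {i}: {exc}") from exc
        if rec.species_name in seen:
            raise SpeciesTableError(f"row {i}: duplicate species_name {rec.species_name!r}")
        seen.add(rec.species_name)
        records.append(rec)
    return records


def write_species_table(
    records: Sequence[SpeciesRecord],
    path: str | Path,
    *,
    delimiter: str = ",",
    set_delimiter: str = SET_DELIMITER,
) -> None:
    """Write records to CSV; inverse of :func:`load_species_table`."""
    rows = []
    for r in records:
        rows.append(
            {
                "species_name": r.species_name,
                "family": r.family,
                "form": r.form.value,
                "parts": set_delimiter.join(sorted(p.value for p in r.parts)),
                "thermal_climates": set_delimiter.join(
                    sorted(c.value for c in r.thermal_climates)
                ),
                "moisture": set_delimiter.join(sorted(m.value for m in r.moisture)),
                "shade": r.shade.value,
                "domestication": r.domestication.value,
                "lifecycle": r.lifecycle.value,
            }
        )
    pd.DataFrame(rows, columns=_REQUIRED_COLUMNS).to_csv(
        path, sep=delimiter, index=False
    )


_SINGLE_FIELDS = {"form", "shade", "domestication", "lifecycle"}
_SET_FIELDS = {"parts", "thermal_climates", "moisture"}


def breakdown(
    records: Sequence[SpeciesRecord],
    category_field: str,
    *,
    single_count: bool = False,
    climate_rollup: bool = False,
) -> CategoryBreakdown:
    """Tabulate a categorical trait over a species table.

    Single-valued traits count each species once; set-valued traits count a
    species once per value it carries (the convention used in published
    part-used and climate charts), unless ``single_count`` collapses each
    species to its set of values but keeps the species count as denominator.
    ``climate_rollup`` maps the seven thermal climates onto the three broad
    bands tropical / temperate / boreal_arctic before counting.
    """
    if category_field not in _SINGLE_FIELDS | _SET_FIELDS:
        raise ValueError(f"unknown category field {category_field!r}")
    counts: dict[str, int] = {}

    if category_field in _SINGLE_FIELDS:
        for r in records:
            key = getattr(r, category_field).value
            counts[key] = counts.get(key, 0) + 1
        return CategoryBreakdown(category_field, counts, len(records), False)

    def values_of(r: SpeciesRecord) -> set[str]:
        vals = getattr(r, category_field)
        if climate_rollup and category_field == "thermal_climates":
            return {
                band
                for band, members in CLIMATE_ROLLUP.items()
                if vals & members
            }
        return {v.value for v in vals}

    total = 0
    for r in records:
        for key in values_of(r):
            counts[key] = counts.get(key, 0) + 1
            total += 1
    if single_count:
        return CategoryBreakdown(category_field, counts, len(records), True)
    return CategoryBreakdown(category_field, counts, total, True)


def perennial_share(
    n_fully_perennial: int, n_perennial_as_annual: int, n_total_vegetables: int
) -> tuple[float, float]:
    """Bounds on the PV share of cultivated vegetable species, in percent.

    The lower bound counts only fully perennial crops; the upper bound also
    admits perennials commonly grown as annuals.
    """
    if n_total_vegetables <= 0:
        raise ValueError("total vegetable count must be positive")
    if n_fully_perennial + n_perennial_as_annual > n_total_vegetables:
        raise ValueError("perennial counts exceed total")
    lower = 100.0 * n_fully_perennial / n_total_vegetables
    upper = 100.0 * (n_fully_perennial + n_perennial_as_annual) / n_total_vegetables
    return lower, upper


def domestication_share(n_in_class: int, n_total: int) -> float:
    """Percentage of species in one domestication class, to one decimal."""
    if n_total <= 0:
        raise ValueError("total count must be positive")
    if not 0 <= n_in_class <= n_total:
        raise ValueError("class count outside [0, total]")
    return round_half_up(100.0 * n_in_class / n_total, 1)


def current_area(components: Iterable[AreaComponent]) -> float:
    """Total current vegetable-use area in Mha, to one decimal."""
    comps = list(components)
    if not comps:
        raise ValueError("no area components given")
    return round_half_up(sum(c.vegetable_area_Mha for c in comps), 1)
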