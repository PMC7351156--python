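"""Composition meta-analysis and multi-nutrient deficiency scoring.

Per-species nutrient profiles are unweighted arithmetic means over literature
sources, on a 100 g fresh-weight basis (dry-basis sources are converted
first). Species are then scored against two deficiency syndromes:

* *traditional malnutrition* — iron, zinc, vitamin A and folate (iodine
  belongs to the syndrome but is absent from terrestrial plants);
* *industrial diet deficiencies* — fiber, calcium, magnesium and the
  antioxidant vitamins A, C and E.

Scoring awards 3 points per extremely-high nutrient, 2 per very-high and
1 per high; a species totalling at least 6 points qualifies as a
"multi-nutrient" crop for that syndrome. Missing data contributes 0 points
rather than disqualifying a species.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from .inventory import Form, Part, SpeciesRecord
from .nutrient_classes import (
    ClassBounds,
    ConcentrationClass,
    Nutrient,
    classify,
    is_superabundant,
)

__all__ = [
    "Syndrome",
    "SYNDROME_NUTRIENTS",
    "CLASS_POINTS",
    "QUALIFYING_SCORE",
    "NutrientMeasurement",
    "NutrientProfile",
    "SyndromeScore",
    "dry_to_fresh",
    "aggregate_profile",
    "combine_parts",
    "score_syndrome",
    "top_n",
    "superabundance_by_category",
    "CategoryNutritionSummary",
]

logger = logging.getLogger(__name__)


class Syndrome(str, enum.Enum):
    traditional = "traditional"
    industrial = "industrial"


SYNDROME_NUTRIENTS: dict[Syndrome, tuple[Nutrient, ...]] = {
    Syndrome.traditional: (Nutrient.Fe, Nutrient.Zn, Nutrient.vitA, Nutrient.folate),
    Syndrome.industrial: (
        Nutrient.fiber,
        Nutrient.Ca,
        Nutrient.Mg,
        Nutrient.vitA,
        Nutrient.vitC,
        Nutrient.vitE,
    ),
}

CLASS_POINTS: dict[ConcentrationClass, int] = {
    ConcentrationClass.extremely_high: 3,
    ConcentrationClass.very_high: 2,
    ConcentrationClass.high: 1,
}

QUALIFYING_SCORE = 6


class NutrientMeasurement(BaseModel):
    """One literature value: a species' nutrient concentration per 100 g,
    on a fresh or dry basis (dry values require the sample's moisture
    fraction so they can be put on the fresh basis)."""

    model_config = ConfigDict(frozen=True)

    species_name: str
    nutrient: Nutrient
    value: float
    basis: str = "fresh"  # "fresh" | "dry"
    moisture_fraction: float | None = None
    source_id: str = ""
    part: str = ""

    @model_validator(mode="after")
    def _check(self) -> "NutrientMeasurement":
        if self.value < 0:
            raise ValueError("concentration must be >= 0")
        if self.basis not in ("fresh", "dry"):
            raise ValueError(f"basis must be 'fresh' or 'dry', got {self.basis!r}")
        if self.basis == "dry":
            if self.moisture_fraction is None:
                raise ValueError("dry-basis measurement requires moisture_fraction")
            if not 0.0 <= self.moisture_fraction < 1.0:
                raise ValueError("moisture_fraction must be in [0, 1)")
        return self

    def fresh_value(self) -> float:
        if self.basis == "fresh":
            return self.value
        return dry_to_fresh(self.value, self.moisture_fraction)


@dataclass(frozen=True)
class NutrientProfile:
    """Mean fresh-weight composition of one species (optionally one part)."""

    species_name: str
    means: dict[Nutrient, float]
    n_sources: dict[Nutrient, int]
    part_scope: str = "combined"

    def classes(
        self, bounds_set: Mapping[Nutrient, ClassBounds]
    ) -> dict[Nutrient, ConcentrationClass]:
        return {
            nutrient: classify(value, bounds_set[nutrient])
            for nutrient, value in self.means.items()
            if nutrient in bounds_set
        }


@dataclass(frozen=True)
class SyndromeScore:
    species_name: str
    syndrome: Syndrome
    points: int
    contributing: dict[Nutrient, ConcentrationClass | None]

    @property
    def qualifies(self) -> bool:
        return self.points >= QUALIFYING_SCORE


def dry_to_fresh(value_dry: float, moisture_fraction: float) -> float:
    """Convert a per-100 g dry-basis concentration to the fresh basis.

    100 g of fresh tissue contains ``1 - moisture_fraction`` times 100 g of
    dry matter, so the fresh-basis concentration is the dry-basis value
    scaled by the dry-matter fraction.
    """
    if value_dry < 0:
        raise ValueError("concentration must be >= 0")
    if not 0.0 <= moisture_fraction < 1.0:
        raise ValueError("moisture_fraction must be in [0, 1)")
    return value_dry * (1.0 - moisture_fraction)


def aggregate_profile(
    measurements: Sequence[NutrientMeasurement], *, part_scope: str = "combined"
) -> NutrientProfile:
    """Mean fresh-basis composition of one species across sources.

    All measurements must share a species name; dry-basis values are
    converted before averaging; the per-nutrient source count is recorded.
    """
    if not measurements:
        raise ValueError("no measurements given")
    names = {m.species_name for m in measurements}
    if len(names) > 1:
        raise ValueError(f"mixed species in input: {sorted(names)}")
    sums: dict[Nutrient, float] = {}
    counts: dict[Nutrient, int] = {}
    for m in measurements:
        sums[m.nutrient] = sums.get(m.nutrient, 0.0) + m.fresh_value()
        counts[m.nutrient] = counts.get(m.nutrient, 0) + 1
    means = {nut: sums[nut] / counts[nut] for nut in sums}
    return NutrientProfile(
        species_name=names.pop(), means=means, n_sources=counts, part_scope=part_scope
    )


def combine_parts(profiles: Sequence[NutrientProfile]) -> NutrientProfile:
    """Species-level profile from part-level profiles: per-nutrient maximum.

    A species rates on its best part for each nutrient — several species
    qualify as multi-nutrient crops only through the combination of parts.
    """
    if not profiles:
        raise ValueError("no profiles given")
    names = {p.species_name for p in profiles}
    if len(names) > 1:
        raise ValueError(f"mixed species in input: {sorted(names)}")
    means: dict[Nutrient, float] = {}
    n_sources: dict[Nutrient, int] = {}
    for p in profiles:
        for nut, val in p.means.items():
            if nut not in means or val > means[nut]:
                means[nut] = val
            n_sources[nut] = n_sources.get(nut, 0) + p.n_sources.get(nut, 0)
    return NutrientProfile(
        species_name=names.pop(), means=means, n_sources=n_sources,
        part_scope="combined",
    )


def score_syndrome(
    profile_classes: Mapping[Nutrient, ConcentrationClass],
    syndrome: Syndrome,
    *,
    species_name: str = "",
) -> SyndromeScore:
    """Score a species' concentration classes against one syndrome.

    Only the syndrome's nutrients contribute; a nutrient with no class
    (missing data) contributes 0 and is recorded as ``None``.
    """
    syndrome = Syndrome(syndrome)
    contributing: dict[Nutrient, ConcentrationClass | None] = {}
    points = 0
    for nutrient in SYNDROME_NUTRIENTS[syndrome]:
        cls = profile_classes.get(nutrient)
        contributing[nutrient] = cls
        if cls is not None:
            points += CLASS_POINTS.get(cls, 0)
    return SyndromeScore(
        species_name=species_name, syndrome=syndrome, points=points,
        contributing=contributing,
    )


def top_n(
    profiles: Sequence[NutrientProfile], nutrient: Nutrient, n: int
) -> list[tuple[str, float]]:
    """Top-``n`` species by concentration of one nutrient, descending; ties
    broken alphabetically; species without data for the nutrient excluded."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(
        (
            (p.species_name, p.means[nutrient])
            for p in profiles
            if nutrient in p.means
        ),
        key=lambda item: (-item[1], item[0]),
    )
    return ranked[:n]


@dataclass(frozen=True)
class CategoryNutritionSummary:
    """Superabundance statistics for one (form, part) cell."""

    form: Form
    part: Part
    n_crops: int
    prop_one_or_more: float
    prop_four_or_more: float


def superabundance_by_category(
    profiles: Sequence[NutrientProfile],
    species_records: Sequence[SpeciesRecord],
    bounds_set: Mapping[Nutrient, ClassBounds],
) -> dict[tuple[Form, Part], CategoryNutritionSummary]:
    """Proportion of crops with superabundant nutrients per (form, part) cell.

    Species join to trait records on name; a profile with no matching record
    is logged and excluded. A multi-part species contributes to every
    (form, part) cell it occupies. Proportions are fractions in [0, 1] over
    the crops in the cell that have any nutrient data.
    """
    by_name = {r.species_name: r for r in species_records}
    cells: dict[tuple[Form, Part], list[int]] = {}
    for profile in profiles:
        record = by_name.get(profile.species_name)
        if record is None:
            logger.warning(
                "no species record for profile %r; excluded", profile.species_name
            )
            continue
        if not profile.means:
            continue
        n_super = sum(
            1 for cls in profile.classes(bounds_set).values() if is_superabundant(cls)
        )
        for part in record.parts:
            cells.setdefault((record.form, part), []).append(n_super)
    out: dict[tuple[Form, Part], CategoryNutritionSummary] = {}
    for (form, part), supers in cells.items():
        n = len(supers)
        out[(form, part)] = CategoryNutritionSummary(
            form=form,
            part=part,
            n_crops=n,
            prop_one_or_more=sum(1 for s in supers if s >= 1) / n,
            prop_four_or_more=sum(1 for s in supers if s >= 4) / n,
        )
    return out
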