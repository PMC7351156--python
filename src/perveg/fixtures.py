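"""Published reference values from the global perennial-vegetable assessment.

These small machine-readable tables carry the study's printed numbers —
sequestration-rate entries, the nutrient classification grid, the
12-scenario results, the two multi-nutrient species lists, the current
cultivated-area components and the reference-crop name list. They are used
as golden values in tests and as ready-made inputs for the scenario engine
and report writers; they contain only values that appear in the published
tables, each row tagged with a short provenance string.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .inventory import AreaComponent, Form, Part
from .nutrient_classes import CLASS_FROM_LABEL, ConcentrationClass, Nutrient
from .nutrient_scoring import Syndrome

__all__ = [
    "SEQUESTRATION_RATE_ENTRIES",
    "PUBLISHED_AVERAGE_RATES",
    "REFERENCE_RANGES",
    "PUBLISHED_CLASS_GRID",
    "PUBLISHED_SCENARIOS",
    "INCONSISTENT_SCENARIO_CELLS",
    "MultiNutrientRow",
    "TRADITIONAL_MULTINUTRIENT",
    "INDUSTRIAL_MULTINUTRIENT",
    "AREA_COMPONENTS",
    "REFERENCE_CROPS",
    "bundle",
]

# ---------------------------------------------------------------------------
# Sequestration-rate study entries (MgC/ha/yr); ranges as (low, high) tuples.

SEQUESTRATION_RATE_ENTRIES: dict[str, list[float | tuple[float, float]]] = {
    # orchard/plantation systems, bamboo, coppiced leaf trees
    "woody": [3.5, 2.6, 5.1, 7.8, 2.1, (1.8, 10.0), (6.0, 13.0), (0.1, 0.5), 1.18],
    # vines, robust herbs, perennial grains, ordinary herbs
    "herbaceous": [(0.3, 0.8), 1.0, (0.3, 0.5), (0.0, 0.1)],
}

#: Printed category averages, used as authoritative rate defaults.
PUBLISHED_AVERAGE_RATES = {"woody": 3.71, "herbaceous": 0.43}

# ---------------------------------------------------------------------------
# Nutrient classification grid.
#
# REFERENCE_RANGES back-derives each nutrient's reference (min, max) from the
# printed grid: the lower edge of the "low" row and the upper edge of the
# "high" row. The fiber and vitamin A rows of the printed grid carry known
# internal inconsistencies and are excluded from exact doubling checks.

REFERENCE_RANGES: dict[Nutrient, tuple[float, float]] = {
    Nutrient.fiber: (0.40, 3.85),
    Nutrient.Ca: (11.85, 238.70),
    Nutrient.Fe: (0.47, 2.11),
    Nutrient.Mg: (11.25, 85.50),
    Nutrient.Zn: (0.16, 0.56),
    Nutrient.vitA: (0.00, 0.55),
    Nutrient.folate: (13.50, 194.00),
    Nutrient.vitC: (5.65, 116.80),
    Nutrient.vitE: (0.05, 2.54),
}

#: Printed six-class grid: nutrient -> class -> (lower, upper); upper None
#: for the open-ended extremely-high row; the vitamin A very-low row is
#: degenerate (reference minimum 0).
PUBLISHED_CLASS_GRID: dict[Nutrient, dict[str, tuple[float, float | None]]] = {
    Nutrient.fiber: {
        "very_low": (0.00, 0.39), "low": (0.40, 1.45), "medium": (1.46, 2.50),
        "high": (2.51, 3.85), "very_high": (3.59, 7.15), "extremely_high": (7.16, None),
    },
    Nutrient.Ca: {
        "very_low": (0.00, 11.84), "low": (11.85, 86.71), "medium": (86.72, 161.57),
        "high": (161.58, 238.70), "very_high": (238.71, 477.40),
        "extremely_high": (477.41, None),
    },
    Nutrient.Fe: {
        "very_low": (0.00, 0.46), "low": (0.47, 1.01), "medium": (1.02, 1.55),
        "high": (1.56, 2.11), "very_high": (2.12, 4.21), "extremely_high": (4.22, None),
    },
    Nutrient.Mg: {
        "very_low": (0.00, 11.24), "low": (11.25, 35.75), "medium": (35.76, 60.26),
        "high": (60.27, 85.50), "very_high": (85.51, 171.00),
        "extremely_high": (171.01, None),
    },
    Nutrient.Zn: {
        "very_low": (0.00, 0.15), "low": (0.16, 0.29), "medium": (0.30, 0.42),
        "high": (0.43, 0.56), "very_high": (0.57, 1.12), "extremely_high": (1.13, None),
    },
    Nutrient.vitA: {
        "very_low": (0.00, 0.00), "low": (0.00, 0.18), "medium": (0.19, 0.37),
        "high": (0.38, 0.55), "very_high": (0.56, 1.11), "extremely_high": (1.12, None),
    },
    Nutrient.folate: {
        "very_low": (0.00, 13.49), "low": (13.50, 73.07), "medium": (73.08, 132.63),
        "high": (132.64, 194.00), "very_high": (194.01, 388.00),
        "extremely_high": (388.01, None),
    },
    Nutrient.vitC: {
        "very_low": (0.00, 5.64), "low": (5.65, 42.33), "medium": (42.34, 79.01),
        "high": (79.02, 116.80), "very_high": (116.81, 233.59),
        "extremely_high": (233.60, None),
    },
    Nutrient.vitE: {
        "very_low": (0.00, 0.04), "low": (0.05, 0.73), "medium": (0.74, 1.42),
        "high": (1.43, 2.54), "very_high": (2.55, 5.08), "extremely_high": (5.09, None),
    },
}

#: Nutrients whose printed rows are internally consistent with the doubling
#: rule (2 x reference max = very-high upper edge) at printed precision.
DOUBLING_CONSISTENT_NUTRIENTS = (
    Nutrient.Ca, Nutrient.Fe, Nutrient.Mg, Nutrient.Zn,
    Nutrient.folate, Nutrient.vitC, Nutrient.vitE,
)

# ---------------------------------------------------------------------------
# Published 12-scenario grid: id -> (world area Mha, curve, woody fraction,
# woody Mha, woody CO2, non-woody Mha, non-woody CO2, total Mha, total CO2).

PUBLISHED_SCENARIOS: dict[str, tuple] = {
    "1a": (58.2, "linear", 0.25, 1.2, 4.6, 3.7, 5.8, 4.9, 22.7),
    "1b": (58.2, "linear", 0.50, 2.5, 33.8, 2.5, 3.9, 4.9, 37.7),
    "1c": (58.2, "linear", 0.75, 3.7, 50.7, 1.2, 1.9, 4.9, 52.6),
    "2a": (58.2, "exponential", 0.25, 2.2, 30.0, 6.6, 10.4, 8.8, 40.4),
    "2b": (58.2, "exponential", 0.50, 4.4, 60.0, 4.4, 6.9, 8.8, 67.0),
    "2c": (58.2, "exponential", 0.75, 6.6, 90.1, 2.2, 3.5, 8.8, 93.5),
    "3a": (174.5, "linear", 0.25, 3.7, 50.7, 11.1, 17.5, 14.8, 68.2),
    "3b": (174.5, "linear", 0.50, 7.4, 101.3, 7.4, 11.7, 14.8, 113.0),
    "3c": (174.5, "linear", 0.75, 11.1, 152.0, 3.7, 5.8, 14.8, 157.8),
    "4a": (174.5, "exponential", 0.25, 6.6, 90.1, 19.8, 31.2, 26.4, 121.2),
    "4b": (174.5, "exponential", 0.50, 13.2, 180.1, 13.2, 20.8, 26.4, 200.9),
    "4c": (174.5, "exponential", 0.75, 19.8, 270.2, 6.6, 10.4, 26.4, 280.6),
}

#: Published per-curve new-adoption totals (Mha) behind the grid.
PUBLISHED_TOTALS = {"1": 4.9, "2": 8.8, "3": 14.8, "4": 26.4}

#: Cells of the published grid known to be arithmetically inconsistent
#: (row 1a's woody figures cannot be reproduced from its own areas and
#: rates); excluded from golden comparisons.
INCONSISTENT_SCENARIO_CELLS = {("1a", "woody_co2"), ("1a", "total_co2")}


# ---------------------------------------------------------------------------
# Multi-nutrient species lists with printed class labels.


@dataclass(frozen=True)
class MultiNutrientRow:
    species_name: str
    form: Form
    parts: frozenset[Part]
    classes: dict[Nutrient, ConcentrationClass]
    provenance: str


def _row(
    name: str, form: Form, parts: set[Part], labels: Mapping[Nutrient, str], prov: str
) -> MultiNutrientRow:
    return MultiNutrientRow(
        species_name=name,
        form=form,
        parts=frozenset(parts),
        classes={n: CLASS_FROM_LABEL[lbl] for n, lbl in labels.items()},
        provenance=prov,
    )


_W, _V, _H = Form.woody, Form.vine, Form.herb
_LF, _SH, _FB, _UF, _RF, _ST = (
    Part.leaf, Part.shoot, Part.flowerbud, Part.unripe_fruit, Part.ripe_fruit, Part.stem,
)
Fe, Zn, A, B9 = Nutrient.Fe, Nutrient.Zn, Nutrient.vitA, Nutrient.folate
Fb, Ca, Mg, C, E = Nutrient.fiber, Nutrient.Ca, Nutrient.Mg, Nutrient.vitC, Nutrient.vitE

#: 16 multi-nutrient species for traditional malnutrition (Fe/Zn/A/folate).
TRADITIONAL_MULTINUTRIENT: list[MultiNutrientRow] = [
    _row("Cnidoscolus aconitifolius", _W, {_LF}, {Fe: "XH", A: "XH"}, "traditional list row 1"),
    _row("Malva sylvestris", _H, {_LF}, {Fe: "XH", Zn: "XH"}, "traditional list row 2"),
    _row("Manihot esculenta", _W, {_LF}, {Fe: "XH", Zn: "XH", A: "VH"}, "traditional list row 3"),
    _row("Momordica cochinchinensis", _V, {_LF, _UF, _RF},
         {Fe: "VH", Zn: "VH", A: "VH", B9: "H"}, "traditional list row 4"),
    _row("Monochoria vaginalis", _H, {_LF}, {Fe: "VH", Zn: "VH", A: "VH"}, "traditional list row 5"),
    _row("Moringa oleifera", _W, {_LF, _UF, _FB}, {Fe: "XH", Zn: "VH", A: "VH"}, "traditional list row 6"),
    _row("Morus alba", _W, {_LF}, {Fe: "XH", Zn: "XH", A: "VH"}, "traditional list row 7"),
    _row("Persicaria barbata", _H, {_LF}, {Fe: "XH", Zn: "VH", B9: "VH"}, "traditional list row 8"),
    _row("Pterocarpus mildbraedii", _W, {_LF}, {Fe: "XH", Zn: "XH"}, "traditional list row 9"),
    _row("Salix reticulata", _W, {_LF}, {Fe: "XH", Zn: "XH"}, "traditional list row 10"),
    _row("Senna obtusifolia", _W, {_LF}, {Fe: "XH", A: "XH"}, "traditional list row 11"),
    _row("Senna sophera", _W, {_LF}, {Fe: "VH", Zn: "VH", A: "VH", B9: "H"}, "traditional list row 12"),
    _row("Solanum aethiopicum", _H, {_LF}, {Fe: "XH", Zn: "VH", A: "VH"}, "traditional list row 13"),
    _row("Toona sinensis", _W, {_LF}, {Fe: "XH", Zn: "XH", A: "XH"}, "traditional list row 14"),
    _row("Ulmus pumila", _W, {_RF}, {Fe: "XH", Zn: "XH"}, "traditional list row 15"),
    _row("Vitis vinifera", _V, {_LF}, {Fe: "VH", Zn: "VH", A: "VH"}, "traditional list row 16"),
]

#: 24 multi-nutrient species for industrial diet deficiencies
#: (fiber/Ca/Mg/A/C/E).
INDUSTRIAL_MULTINUTRIENT: list[MultiNutrientRow] = [
    _row("Asclepias syriaca", _H, {_LF}, {Ca: "VH", A: "VH", C: "XH"}, "industrial list row 1"),
    _row("Atriplex halimus", _W, {_LF}, {Fb: "VH", Ca: "XH", Mg: "XH"}, "industrial list row 2"),
    _row("Bambusa polymorpha", _W, {_SH}, {Fb: "VH", Ca: "VH", Mg: "VH"}, "industrial list row 3"),
    _row("Cnidoscolus aconitifolius", _W, {_LF}, {Ca: "VH", Mg: "VH", A: "XH", C: "VH"}, "industrial list row 4"),
    _row("Coccinia grandis", _V, {_LF, _UF}, {Fb: "VH", A: "H", E: "XH"}, "industrial list row 5"),
    _row("Dicliptera chinensis", _H, {_LF}, {Ca: "VH", A: "VH", E: "XH"}, "industrial list row 6"),
    _row("Epilobium angustifolium", _H, {_SH}, {Fb: "H", Ca: "H", Mg: "VH", C: "VH"}, "industrial list row 7"),
    _row("Gnetum gnemon", _W, {_LF}, {Fb: "VH", Mg: "H", A: "H", C: "VH", E: "H"}, "industrial list row 8"),
    _row("Limnocharis flava", _H, {_LF, _ST, _FB}, {Fb: "VH", Ca: "XH", Mg: "XH", A: "H"}, "industrial list row 9"),
    _row("Manihot esculenta", _W, {_LF}, {Fb: "H", Ca: "VH", A: "VH", C: "XH", E: "XH"}, "industrial list row 10"),
    _row("Momordica cochinchinensis", _V, {_LF, _UF, _RF},
         {Fb: "H", Ca: "VH", A: "VH", C: "XH", E: "XH"}, "industrial list row 11"),
    _row("Moringa oleifera", _W, {_LF, _UF, _FB},
         {Fb: "H", Ca: "VH", Mg: "VH", A: "VH", C: "VH", E: "H"}, "industrial list row 12"),
    _row("Morus alba", _W, {_LF}, {Fb: "VH", Ca: "VH", Mg: "VH", A: "VH", C: "VH"}, "industrial list row 13"),
    _row("Pisonia umbellifera", _W, {_LF}, {Fb: "VH", Ca: "VH", Mg: "VH"}, "industrial list row 14"),
    _row("Sauropus androgynus", _W, {_LF}, {A: "VH", C: "VH", E: "XH"}, "industrial list row 15"),
    _row("Senna obtusifolia", _W, {_LF}, {Ca: "VH", A: "XH", C: "VH"}, "industrial list row 16"),
    _row("Senna sophera", _W, {_LF}, {Ca: "H", A: "VH", C: "VH", E: "VH"}, "industrial list row 17"),
    _row("Sesbania grandiflora", _W, {_LF}, {Fb: "XH", Ca: "VH", Mg: "VH", C: "H", E: "H"}, "industrial list row 18"),
    _row("Silene vulgaris", _H, {_LF}, {Fb: "VH", A: "VH", E: "XH"}, "industrial list row 19"),
    _row("Solanum aethiopicum", _H, {_LF}, {Ca: "VH", A: "VH", E: "XH"}, "industrial list row 20"),
    _row("Toona sinensis", _W, {_LF}, {Ca: "VH", A: "XH", C: "VH", E: "XH"}, "industrial list row 21"),
    _row("Trichanthera gigantea", _W, {_LF}, {Ca: "XH", Mg: "XH"}, "industrial list row 22"),
    _row("Urtica dioica", _H, {_LF}, {Fb: "H", Ca: "VH", Mg: "H", C: "VH", E: "XH"}, "industrial list row 23"),
    _row("Vitis vinifera", _V, {_LF}, {Fb: "XH", Ca: "VH", Mg: "VH", A: "VH", E: "H"}, "industrial list row 24"),
]

SYNDROME_FIXTURES = {
    Syndrome.traditional: TRADITIONAL_MULTINUTRIENT,
    Syndrome.industrial: INDUSTRIAL_MULTINUTRIENT,
}

# ---------------------------------------------------------------------------
# Current cultivated-area components (Mha) and the reference crop list.

AREA_COMPONENTS: list[AreaComponent] = [
    AreaComponent("olive (table)", 10.6, 0.10),
    AreaComponent("asparagus", 1.5, 1.0),
    AreaComponent("avocado", 0.6, 1.0),
    AreaComponent("globe artichoke", 0.1, 1.0),
    AreaComponent("moringa", 0.038, 1.0),
]

#: The 22 widely grown and marketed reference vegetable crops (cassava leaf
#: is tracked too but excluded as an outlier by default).
REFERENCE_CROPS: list[str] = [
    "Abelmoschus esculentus",
    "Allium ampeloprasum",
    "Allium fistulosum",
    "Asparagus officinalis",
    "Brassica oleracea Italica",
    "Brassica oleracea Capitata",
    "Brassica oleracea Botrytis",
    "Brassica oleracea Acephala",
    "Brassica rapa",
    "Capsicum annuum",
    "Cucumis sativus",
    "Cucurbita summer",
    "Cucurbita winter",
    "Cynara scolymus",
    "Lactuca sativa",
    "Persea americana",
    "Phaseolus vulgaris",
    "Pisum sativum",
    "Solanum lycopersicum",
    "Solanum melongena",
    "Spinacea oleracea",
    "Zea mays",
]

CASSAVA_LEAF = "Manihot esculenta (leaf)"


def bundle() -> dict:
    """All published-value fixtures as one mapping."""
    return {
        "sequestration_rate_entries": SEQUESTRATION_RATE_ENTRIES,
        "published_average_rates": PUBLISHED_AVERAGE_RATES,
        "reference_ranges": REFERENCE_RANGES,
        "published_class_grid": PUBLISHED_CLASS_GRID,
        "published_scenarios": PUBLISHED_SCENARIOS,
        "published_totals": PUBLISHED_TOTALS,
        "traditional_multinutrient": TRADITIONAL_MULTINUTRIENT,
        "industrial_multinutrient": INDUSTRIAL_MULTINUTRIENT,
        "area_components": AREA_COMPONENTS,
        "reference_crops": REFERENCE_CROPS,
    }
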