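"""Report writers: render pipeline results as tidy CSV/JSON tables.

Layouts mirror the published tables: the six-class nutrient bounds grid,
the 12-row scenario grid, multi-nutrient species lists with XH/VH/H labels,
top-ten rankings, and categorical breakdowns. Display rounding is 1 decimal
for Mha and MMT CO2-eq, 2 decimals for nutrient bounds, and full precision
plus a rounded column for percentages.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from ._util import round_half_up
from .carbon import Scenario
from .inventory import CategoryBreakdown
from .nutrient_classes import ClassBounds, ConcentrationClass, Nutrient
from .nutrient_scoring import SyndromeScore

__all__ = [
    "render_bounds",
    "render_scenarios",
    "render_multinutrient",
    "render_topten",
    "render_breakdown",
    "render_table",
]

_CLASS_ROWS = [
    ("very_low", ConcentrationClass.very_low),
    ("low", ConcentrationClass.low),
    ("medium", ConcentrationClass.medium),
    ("high", ConcentrationClass.high),
    ("very_high", ConcentrationClass.very_high),
    ("extremely_high", ConcentrationClass.extremely_high),
]


def render_bounds(bounds_set: Mapping[Nutrient, ClassBounds]) -> pd.DataFrame:
    """Six class rows x one column per nutrient, 2-decimal display rounding.

    Each cell shows the class interval as ``lower-upper`` (the top class is
    open-ended, ``lower+``); a nutrient without a very-low class leaves that
    cell empty.
    """
    nutrients = [n for n in Nutrient if n in bounds_set]
    data: dict[str, list[str]] = {}
    for nutrient in nutrients:
        b = bounds_set[nutrient]
        fmt = lambda x: f"{round_half_up(x, 2):.2f}"
        edges = {
            "very_low": (0.0, b.ref_min) if b.has_very_low else None,
            "low": (b.ref_min if b.has_very_low else 0.0, b.t1),
            "medium": (b.t1, b.t2),
            "high": (b.t2, b.ref_max),
            "very_high": (b.ref_max, b.vh_upper),
            "extremely_high": (b.vh_upper, None),
        }
        col = []
        for name, _ in _CLASS_ROWS:
            interval = edges[name]
            if interval is None:
                col.append("")
            elif interval[1] is None:
                col.append(f"{fmt(interval[0])}+")
            else:
                col.append(f"{fmt(interval[0])}-{fmt(interval[1])}")
        data[nutrient.value] = col
    return pd.DataFrame(data, index=[name for name, _ in _CLASS_ROWS])


_SCENARIO_COLUMNS = [
    "scenario",
    "world_veg_area_Mha",
    "adoption_curve",
    "woody_fraction",
    "woody_Mha",
    "woody_MMT_co2eq_yr",
    "nonwoody_Mha",
    "nonwoody_MMT_co2eq_yr",
    "total_Mha",
    "total_MMT_co2eq_yr",
]


def render_scenarios(scenarios: Sequence[Scenario]) -> pd.DataFrame:
    """12 rows x 10 columns in the published scenario-grid order."""
    rows = []
    for s in scenarios:
        rows.append(
            {
                "scenario": s.id,
                "world_veg_area_Mha": s.world_veg_area,
                "adoption_curve": s.curve,
                "woody_fraction": s.woody_fraction,
                "woody_Mha": round_half_up(s.woody_Mha, 1),
                "woody_MMT_co2eq_yr": round_half_up(s.woody_co2, 1),
                "nonwoody_Mha": round_half_up(s.nonwoody_Mha, 1),
                "nonwoody_MMT_co2eq_yr": round_half_up(s.nonwoody_co2, 1),
                "total_Mha": round_half_up(s.total_Mha, 1),
                "total_MMT_co2eq_yr": round_half_up(s.total_co2, 1),
            }
        )
    return pd.DataFrame(rows, columns=_SCENARIO_COLUMNS)


def render_multinutrient(scores: Sequence[SyndromeScore]) -> pd.DataFrame:
    """Qualifying species with per-nutrient XH/VH/H labels and points."""
    rows = []
    for score in scores:
        if not score.qualifies:
            continue
        row: dict = {"species_name": score.species_name, "points": score.points}
        for nutrient, cls in score.contributing.items():
            row[nutrient.value] = cls.label if cls is not None else ""
        rows.append(row)
    return pd.DataFrame(rows).sort_values("species_name").reset_index(drop=True) if rows else pd.DataFrame(
        columns=["species_name", "points"]
    )


def render_topten(ranked: Sequence[tuple[str, float]], nutrient: Nutrient) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": range(1, len(ranked) + 1),
            "species_name": [name for name, _ in ranked],
            nutrient.value: [value for _, value in ranked],
        }
    )


def render_breakdown(bd: CategoryBreakdown) -> pd.DataFrame:
    cats = sorted(bd.counts)
    pct = bd.percentages
    return pd.DataFrame(
        {
            "category": cats,
            "count": [bd.counts[c] for c in cats],
            "percent": [round_half_up(pct[c], 1) for c in cats],
        }
    )


_LAYOUTS = {
    "bounds": render_bounds,
    "scenarios": render_scenarios,
    "multinutrient": render_multinutrient,
    "breakdown": render_breakdown,
}


def render_table(result, layout: str, **kwargs) -> pd.DataFrame:
    """Dispatch a result object to its layout renderer."""
    if layout == "topten":
        return render_topten(result, **kwargs)
    try:
        renderer = _LAYOUTS[layout]
    except KeyError:
        raise ValueError(f"unknown layout {layout!r}") from None
    try:
        return renderer(result, **kwargs)
    except (AttributeError, TypeError, KeyError) as exc:
        raise ValueError(f"result does not match layout {layout!r}: {exc}") from exc
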