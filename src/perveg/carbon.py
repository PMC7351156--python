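"""Carbon-sequestration scenario modelling for new PV adoption.

The projection chain is:

1. fit a linear or exponential (log-linear) trend to the historical
   cultivated-area series of the four globally tracked PV commodity crops
   (artichoke, asparagus, avocado, olive), summed into one series;
2. new adoption by 2050 = max(0, projected(2050) - projected(2020));
3. optionally rescale adoption for a world vegetable area that grows from
   the current 58.2 Mha to the 174.5 Mha needed for universal healthy diets;
4. split new adoption between woody and non-woody PVs (25/50/75% woody);
5. convert area to annual sequestration: Mha x MgC/ha/yr gives MMT C/yr,
   times 44/12 gives MMT CO2-eq/yr.

Default rates are 3.71 MgC/ha/yr for woody perennials and 0.43 for vines
and herbs — literature averages adopted as authoritative configuration; the
:func:`average_rate` helper recomputes an average from individual study
entries under an explicit range-resolution policy.

Trend fitting follows the model/results convention: :class:`AdoptionTrend`
is constructed from a series, ``fit()`` returns
:class:`AdoptionTrendResults` with estimates, standard errors, projections
and a ``summary()`` table (ordinary least squares via statsmodels, on the
log scale for the exponential curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._util import round_half_up

__all__ = [
    "AreaSeries",
    "SequestrationRates",
    "AdoptionTrend",
    "AdoptionTrendResults",
    "AdoptionProjection",
    "Scenario",
    "fit_linear",
    "fit_exponential",
    "scale_for_world_area",
    "allocate",
    "sequestration",
    "average_rate",
    "build_scenario_grid",
    "CO2_PER_C",
    "CURRENT_WORLD_VEG_AREA_MHA",
    "TRIPLED_WORLD_VEG_AREA_MHA",
    "WOODY_FRACTIONS",
]

#: Mass ratio CO2 : C — converts sequestered carbon to CO2 equivalent.
CO2_PER_C = 44.0 / 12.0

CURRENT_WORLD_VEG_AREA_MHA = 58.2
TRIPLED_WORLD_VEG_AREA_MHA = 174.5
WOODY_FRACTIONS = (0.25, 0.50, 0.75)

PROJECTION_BASE_YEAR = 2020
PROJECTION_TARGET_YEAR = 2050


@dataclass(frozen=True)
class AreaSeries:
    """A crop-area time series (year, Mha), strictly increasing in year."""

    label: str
    years: tuple[int, ...]
    areas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.years) != len(self.areas):
            raise ValueError("years and areas differ in length")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        if any(a < 0 for a in self.areas):
            raise ValueError("areas must be >= 0")

    @classmethod
    def from_points(cls, label: str, points: Iterable[tuple[int, float]]) -> "AreaSeries":
        pts = list(points)
        return cls(label, tuple(y for y, _ in pts), tuple(a for _, a in pts))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, label: str = "total") -> "AreaSeries":
        """Sum per-crop rows of a ``crop,year,area_mha`` frame into one
        combined series (the four tracked crops are projected jointly)."""
        grouped = df.groupby("year")["area_mha"].sum().sort_index()
        return cls(label, tuple(int(y) for y in grouped.index), tuple(grouped.values))

    def __len__(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class SequestrationRates:
    """Per-hectare sequestration rates (MgC/ha/yr) and the C->CO2 factor."""

    woody_rate: float = 3.71
    herbaceous_rate: float = 0.43
    co2_per_c: float = CO2_PER_C

    def __post_init__(self) -> None:
        if self.woody_rate < 0 or self.herbaceous_rate < 0 or self.co2_per_c <= 0:
            raise ValueError("rates must be >= 0 and co2_per_c > 0")


class AdoptionTrend:
    """Trend model for a cultivated-area series.

    Parameters
    ----------
    series : AreaSeries
        Historical (year, Mha) observations; at least three points.
    curve : {"linear", "exponential"}
        ``linear`` regresses area on year by OLS; ``exponential`` regresses
        log(area) on year (all areas must then be positive).
    """

    def __init__(self, series: AreaSeries, curve: Literal["linear", "exponential"] = "linear"):
        if len(series) < 3:
            raise ValueError("need at least 3 points to fit a trend")
        if curve not in ("linear", "exponential"):
            raise ValueError(f"unknown curve {curve!r}")
        if curve == "exponential" and any(a <= 0 for a in series.areas):
            raise ValueError("exponential trend requires strictly positive areas")
        self.series = series
        self.curve = curve

    def fit(self) -> "AdoptionTrendResults":
        years = np.asarray(self.series.years, dtype=float)
        y = np.asarray(self.series.areas, dtype=float)
        if self.curve == "exponential":
            y = np.log(y)
        X = sm.add_constant(years)
        res = sm.OLS(y, X).fit()
        return AdoptionTrendResults(model=self, _sm_results=res)


@dataclass(frozen=True)
class AdoptionTrendResults:
    """Fitted adoption trend: parameters, uncertainty, projections."""

    model: AdoptionTrend
    _sm_results: object = field(repr=False)

    @property
    def params(self) -> tuple[float, float]:
        """(intercept, slope) for linear; (log-intercept, growth rate) for
        exponential."""
        p = self._sm_results.params
        return float(p[0]), float(p[1])

    @property
    def bse(self) -> tuple[float, float]:
        se = self._sm_results.bse
        return float(se[0]), float(se[1])

    @property
    def slope(self) -> float:
        """Mha/yr (linear) or per-year exponential growth rate."""
        return self.params[1]

    @property
    def rsquared(self) -> float:
        return float(self._sm_results.rsquared)

    def projected(self, year: float) -> float:
        """Trend value at ``year``, in Mha, clamped at 0."""
        intercept, slope = self.params
        if self.model.curve == "exponential":
            value = float(np.exp(intercept + slope * year))
        else:
            value = intercept + slope * year
        return max(0.0, value)

    def new_adoption(
        self,
        base_year: int = PROJECTION_BASE_YEAR,
        target_year: int = PROJECTION_TARGET_YEAR,
    ) -> float:
        """Projected area growth between the base and target years (Mha),
        floored at 0."""
        return max(0.0, self.projected(target_year) - self.projected(base_year))

    def to_projection(self) -> "AdoptionProjection":
        return AdoptionProjection(
            curve=self.model.curve,
            fitted_params=self.params,
            new_adoption_2050=self.new_adoption(),
        )

    def summary(self) -> str:
        intercept, slope = self.params
        se0, se1 = self.bse
        name = "slope (Mha/yr)" if self.model.curve == "linear" else "growth rate (/yr)"
        lines = [
            f"Adoption trend: {self.model.curve} fit to {self.model.series.label!r} "
            f"({len(self.model.series)} points, "
            f"{self.model.series.years[0]}-{self.model.series.years[-1]})",
            f"  intercept        {intercept:12.5g}  (se {se0:.3g})",
            f"  {name:<16} {slope:12.5g}  (se {se1:.3g})",
            f"  R-squared        {self.rsquared:12.4f}",
            f"  projected {PROJECTION_BASE_YEAR}: {self.projected(PROJECTION_BASE_YEAR):.2f} Mha; "
            f"projected {PROJECTION_TARGET_YEAR}: {self.projected(PROJECTION_TARGET_YEAR):.2f} Mha",
            f"  new adoption {PROJECTION_BASE_YEAR}-{PROJECTION_TARGET_YEAR}: "
            f"{self.new_adoption():.2f} Mha",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class AdoptionProjection:
    """Compact record of a fitted curve and its 2050 new-adoption figure."""

    curve: str
    fitted_params: tuple[float, float]
    new_adoption_2050: float


def fit_linear(series: AreaSeries) -> AdoptionProjection:
    """OLS linear trend; convenience wrapper over :class:`AdoptionTrend`."""
    return AdoptionTrend(series, "linear").fit().to_projection()


def fit_exponential(series: AreaSeries) -> AdoptionProjection:
    """Log-linear (exponential) trend; wrapper over :class:`AdoptionTrend`."""
    return AdoptionTrend(series, "exponential").fit().to_projection()


def scale_for_world_area(
    base_new_adoption: float, base_world_area: float, target_world_area: float
) -> float:
    """Rescale a new-adoption figure proportionally to world vegetable area."""
    if base_world_area <= 0:
        raise ValueError("base world area must be positive")
    return base_new_adoption * target_world_area / base_world_area


def allocate(total_new: float, woody_fraction: float) -> tuple[float, float]:
    """Split total new adoption (Mha) into (woody, non-woody) components."""
    if not 0.0 <= woody_fraction <= 1.0:
        raise ValueError("woody_fraction must be in [0, 1]")
    if total_new < 0:
        raise ValueError("total_new must be >= 0")
    woody = total_new * woody_fraction
    return woody, total_new - woody


def sequestration(area_Mha: float, rate: float, co2_per_c: float = CO2_PER_C) -> float:
    """Annual sequestration in MMT CO2-eq/yr for an area at a given rate.

    1 Mha x 1 MgC/ha/yr = 1 MMT C/yr; the CO2:C mass ratio converts to
    CO2 equivalent.
    """
    if area_Mha < 0 or rate < 0:
        raise ValueError("area and rate must be >= 0")
    return area_Mha * rate * co2_per_c


RateEntry = float | tuple[float, float]


def average_rate(
    entries: Sequence[RateEntry], policy: Literal["midpoint", "low", "high"] = "midpoint"
) -> float:
    """Arithmetic mean of study rates, resolving (low, high) ranges first.

    ``midpoint`` takes the centre of each range, ``low``/``high`` its
    endpoints.
    """
    if not entries:
        raise ValueError("no rate entries given")
    resolved = []
    for e in entries:
        if isinstance(e, tuple):
            lo, hi = e
            resolved.append({"midpoint": (lo + hi) / 2.0, "low": lo, "high": hi}[policy])
        else:
            resolved.append(float(e))
    return sum(resolved) / len(resolved)


@dataclass(frozen=True)
class Scenario:
    """One cell of the 12-scenario grid.

    Ids follow the published numbering: 1 = current world area / linear,
    2 = current / exponential, 3 = tripled / linear, 4 = tripled /
    exponential; letters a/b/c = 25/50/75% woody. Areas are rounded to the
    reporting precision (0.1 Mha) before sequestration is computed, so the
    printed component rows are mutually consistent.
    """

    id: str
    world_veg_area: float
    curve: str
    woody_fraction: float
    total_Mha: float
    woody_Mha: float
    nonwoody_Mha: float
    woody_co2: float
    nonwoody_co2: float

    @property
    def total_co2(self) -> float:
        return self.woody_co2 + self.nonwoody_co2


def build_scenario_grid(
    projections: Mapping[str, float],
    rates: SequestrationRates = SequestrationRates(),
    woody_fractions: Sequence[float] = WOODY_FRACTIONS,
    world_areas: Sequence[float] = (CURRENT_WORLD_VEG_AREA_MHA, TRIPLED_WORLD_VEG_AREA_MHA),
    *,
    totals_override: Mapping[str, float] | None = None,
    area_decimals: int | None = 1,
) -> list[Scenario]:
    """Build the full scenario grid: 2 curves x 2 world areas x woody splits.

    Parameters
    ----------
    projections
        ``{"linear": Mha, "exponential": Mha}`` — new adoption by 2050 at
        the current world vegetable area.
    totals_override
        Optional ``{scenario number ("1".."4"): total Mha}`` to inject
        published totals directly, bypassing fitting and rescaling.
    area_decimals
        Allocated areas are rounded half-up to this many decimals before
        sequestration (None disables rounding).
    """
    curves = ("linear", "exponential")
    for c in curves:
        if c not in projections:
            raise ValueError(f"projections must provide {c!r}")
    letters = "abc"
    if len(woody_fractions) != len(letters):
        raise ValueError("expected exactly three woody fractions (a/b/c)")

    scenarios: list[Scenario] = []
    number = 0
    for world_area in world_areas:
        for curve in curves:
            number += 1
            base_total = projections[curve]
            total = scale_for_world_area(
                base_total, CURRENT_WORLD_VEG_AREA_MHA, world_area
            )
            if totals_override and str(number) in totals_override:
                total = float(totals_override[str(number)])
            for letter, wf in zip(letters, woody_fractions):
                woody, nonwoody = allocate(total, wf)
                if area_decimals is not None:
                    woody = round_half_up(woody, area_decimals)
                    nonwoody = round_half_up(nonwoody, area_decimals)
                scenarios.append(
                    Scenario(
                        id=f"{number}{letter}",
                        world_veg_area=world_area,
                        curve=curve,
                        woody_fraction=wf,
                        total_Mha=total,
                        woody_Mha=woody,
                        nonwoody_Mha=nonwoody,
                        woody_co2=sequestration(
                            woody, rates.woody_rate, rates.co2_per_c
                        ),
                        nonwoody_co2=sequestration(
                            nonwoody, rates.herbaceous_rate, rates.co2_per_c
                        ),
                    )
                )
    return scenarios
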