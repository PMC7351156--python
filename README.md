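# perveg

Analytics for cultivated **perennial vegetables** (PVs) — perennial crops
(living ≥ 3 years, giving more than one year of harvest) whose vegetative or
reproductive structures are eaten as vegetables. PVs span trees with edible
leaves, bamboos grown for shoots, perennial vines and herbs; they matter for
crop biodiversity, for carbon sequestration on vegetable cropland, and for
addressing micronutrient deficiencies. `perveg` packages the three analyses a
global assessment of this crop class needs, with seeded synthetic-data
generators for every input:

1. **Inventory** — validate species-trait tables (form, parts used, climate,
   moisture, shade, domestication, lifecycle), compute categorical
   breakdowns with the field's multi-count convention for parts and
   climates, and do cultivated-area arithmetic (e.g. only 10% of olive area
   is table olives, hence vegetable land).
2. **Nutrition** — aggregate multi-source composition measurements into mean
   per-100 g fresh-weight profiles (converting dry-basis values by
   `fresh = dry × (1 − moisture)`), classify each nutrient against a
   reference-crop benchmark, score species against two deficiency
   syndromes, and rank top-ten lists.
3. **Carbon** — fit linear/exponential adoption trends to historical crop
   area, project new adoption to 2050, and compute annual CO₂-equivalent
   sequestration under a 12-scenario grid.

## The methods in brief

**Nutrient classes.** For each nutrient (fiber, Ca, Fe, Mg, Zn, vitamins A,
C, E, folate; iodine excluded — terrestrial plants carry none) the range
[min, max] over a 22-crop reference set of widely marketed vegetables is
split into equal tertiles *low / medium / high*; below the reference minimum
is *very low*, (max, 2·max] is *very high*, and > 2·max is *extremely high*.
A nutrient in the top two classes is **superabundant**. Syndrome scoring
awards 3/2/1 points per extremely-high/very-high/high nutrient; ≥ 6 points
qualifies a species as a *multi-nutrient* crop for that syndrome
(traditional malnutrition: Fe, Zn, vit A, folate; industrial diet
deficiencies: fiber, Ca, Mg, vit A, C, E).

**Carbon scenarios.** New adoption A (Mha) by 2050 is
`max(0, f(2050) − f(2020))` for a fitted trend `f` (OLS on area, or on
log-area for the exponential curve), optionally rescaled for a world
vegetable area growing from 58.2 to 174.5 Mha. A woody fraction
w ∈ {0.25, 0.5, 0.75} splits the area, and sequestration is

```
CO2 (MMT CO2-eq/yr) = Mha × rate (MgC/ha/yr) × 44/12
```

with default rates 3.71 (woody) and 0.43 (vines/herbs).

## Worked example

```python
from perveg.carbon import SequestrationRates, build_scenario_grid
from perveg.fixtures import PUBLISHED_TOTALS
from perveg.reporting import render_scenarios

grid = build_scenario_grid(
    {"linear": 4.9, "exponential": 8.8},
    SequestrationRates(woody_rate=3.71, herbaceous_rate=0.43),
    totals_override=PUBLISHED_TOTALS,   # {"1": 4.9, "2": 8.8, "3": 14.8, "4": 26.4}
)
print(render_scenarios(grid).to_string(index=False))
```

prints (excerpt):

```
scenario  world_veg_area_Mha adoption_curve  woody_fraction  woody_Mha  woody_MMT_co2eq_yr  nonwoody_Mha  nonwoody_MMT_co2eq_yr  total_Mha  total_MMT_co2eq_yr
      3a               174.5         linear            0.25        3.7                50.3          11.1                   17.5       14.8                67.8
      4c               174.5    exponential            0.75       19.8               269.3           6.6                   10.4       26.4               279.8
```

Row `3a` reads: if world vegetable area triples and adoption follows the
linear trend, 14.8 Mha of new PVs are planted by 2050; at 25% woody, the
11.1 Mha of non-woody PVs sequester 17.5 MMT CO₂-eq/yr (11.1 × 0.43 × 44/12)
and the 3.7 Mha of woody PVs 50.3 MMT CO₂-eq/yr.

Trend fitting follows the model/results convention:

```python
from perveg.carbon import AdoptionTrend
from perveg.synthetic import SeriesSpec, gen_series

series = gen_series(SeriesSpec(curve="linear", base=2.0, rate=0.163, noise_sd=0.0))
res = AdoptionTrend(series, "linear").fit()
print(res.summary())
```

```
Adoption trend: linear fit to 'synthetic' (51 points, 1967-2017)
  intercept             -318.62  (se 1.3e-12)
  slope (Mha/yr)          0.163  (se 6.52e-16)
  R-squared              1.0000
  projected 2020: 10.64 Mha; projected 2050: 15.53 Mha
  new adoption 2020-2050: 4.89 Mha
```

A `perveg` CLI wraps the same functions (`perveg inventory summarize`,
`perveg nutrition score|topn`, `perveg carbon scenarios`,
`perveg simulate inventory|composition|series`, `perveg report bounds`).

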