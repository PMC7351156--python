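# Methods

This note documents the models and procedures `perveg` implements, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical choices
made where the design was open.

## Scope and data model

The package operates on three kinds of input:

* a **species-trait table** (one row per cultivated PV species: growth form,
  parts eaten, thermal climates, moisture regimes, shade tolerance,
  domestication status, lifecycle), with set-valued cells delimited by `;`;
* a **nutrient-measurement table** (species × nutrient × per-100 g value,
  fresh or dry basis, source id) plus a **reference-crop table** of the 22
  widely marketed benchmark vegetables;
* a **crop-area time series** (`crop,year,area_mha`) for adoption-trend
  fitting, and a JSON scenario configuration.

All validation is up-front (pydantic models, typed enums); malformed rows
fail with the row number and column named, rather than propagating NaNs.

## Inventory accounting

Categorical breakdowns use two denominators. Single-valued traits (form,
shade, domestication, lifecycle) count each species once and percentages sum
to 100 before display rounding. Set-valued traits (parts, climates,
moisture) multi-count a species once per value it carries — the convention
used in the field's published form-by-part charts — with the number of
(species, value) pairs as denominator; a `single_count` flag keeps the
species count as denominator instead. Climate reporting can roll the seven
thermal classes up to tropical / temperate / boreal-arctic bands.

Percentages are computed at full precision and rounded only for display,
half-up (decimal, not binary-float, rounding: `round(2.45) → 2.5`), because
published tables mix one-decimal and integer styles and banker's rounding
would silently disagree with them.

The perennial share of vegetable species is reported as a (lower, upper)
pair: fully perennial crops only, versus also counting perennials commonly
grown as annuals. It is always computed from counts, never hard-coded.

## Nutrient classification

For each nutrient the reference set supplies `ref_min` and `ref_max` over
the crops with data (missing cells are simply excluded; cassava leaf is
excluded by default as an extreme outlier, re-includable by flag). The six
classes are:

| class | interval |
|---|---|
| very low | [0, ref_min) |
| low | [ref_min, t1) |
| medium | [t1, t2) |
| high | [t2, ref_max] |
| very high | (ref_max, 2·ref_max] |
| extremely high | (2·ref_max, ∞) |

with `t1`, `t2` the exact thirds of [ref_min, ref_max]. Two deliberate
numerical choices:

* **Tertiles of the range, not quantiles of the values.** The published
  grids for iron and zinc are consistent only with thirds of (min, max);
  quantile-based tertiles would disagree.
* **Continuous half-open intervals.** Published grids print two-decimal
  bounds with +0.01 offsets between adjacent rows (e.g. high ends at 238.70
  and very-high starts at 238.71). These offsets are display formatting;
  internally the boundaries are continuous, closed at `ref_max` on the high
  side, so classification is total and monotone for every non-negative
  finite value. Where the printed offset lands (very-high upper edge vs
  extremely-high threshold) varies by row in the published grid; tests
  accept either edge at display precision.

When `ref_min = 0` (vitamin A in the published reference set) the very-low
class cannot exist and [0, t1) is low. A nutrient is **superabundant** when
classed very-high or extremely-high, i.e. strictly above the reference
maximum.

Known limitation: the published fiber row is internally inconsistent (its
very-high band does not start at the high band's end, nor double to its own
upper edge), so fiber is never used as a golden value; the doubling rule is
applied uniformly regardless.

## Composition meta-analysis and scoring

Per-species means are unweighted arithmetic means across sources on the
100 g fresh-weight basis; dry-basis sources convert first via
`fresh = dry × (1 − moisture_fraction)`, and the moisture fraction must be
supplied explicitly (published analyses do not state the values they used,
so none are assumed). Source counts per nutrient are retained.

Multi-part species: when a species-level rating is requested, the combined
profile takes the per-nutrient **maximum** across part-level profiles (a
species rates on its best part; several published multi-nutrient species
qualify only through part combination). A per-part mode is available.

Syndrome scoring sums 3/2/1 points for extremely-high/very-high/high
nutrients within the syndrome's set; ≥ 6 points qualifies. Missing data
contributes 0 points rather than disqualifying — published scoring rated
species despite incomplete nutrient coverage — which means scores are lower
bounds under missingness. Rankings break ties alphabetically (the published
procedure is silent; alphabetical is deterministic). Vitamin A stays in
mg RAE; no IU conversion.

## Carbon scenarios

*Trend model.* `AdoptionTrend(series, curve).fit()` runs OLS of area on
calendar year (linear) or of log-area on year (exponential; requires
positive areas). The historical input is the **sum** of the four tracked
commodity PV crops' areas — they are projected jointly, not per crop. New
adoption is `max(0, f(2050) − f(2020))`; projections clamp negative trend
values to zero.

*Scenario grid.* 2 adoption curves × 2 world vegetable areas
(58.2 / 174.5 Mha) × 3 woody fractions (25/50/75%) = 12 scenarios, labelled
1a–4c (1 current/linear, 2 current/exponential, 3 tripled/linear,
4 tripled/exponential; a/b/c by woody fraction). Tripled-area scenarios
scale the base adoption by 174.5/58.2 ≈ 2.998 — proportional to area, not by
exactly 3. Published totals can be injected (`totals_override`) to bypass
fitting and rescaling entirely.

*Sequestration.* `CO2 = Mha × rate × 44/12`. The 44/12 CO₂:C mass ratio is
the standard carbon-accounting conversion and is the only factor consistent
with every published non-woody scenario cell. Rates default to the published
category averages 3.71 (woody) / 0.43 (herbaceous) MgC/ha/yr, taken as
authoritative configuration: recomputing them from the underlying study
entries under any range policy (midpoint/low/high) gives different values
(e.g. herbaceous midpoint 0.50), so `average_rate` exposes the policy
computation but does not override the defaults. Rates are constant — no
soil-carbon saturation or time dynamics.

*Rounding before multiplication.* Allocated areas are rounded half-up to
0.1 Mha **before** sequestration is computed (disable with
`area_decimals=None`). The published grid's cells are mutually consistent
only under this order of operations; computing from unrounded areas
reproduces the non-woody cells but drifts up to 1.4% on woody cells. One
published woody cell (scenario 1a) is inconsistent with its own row under
any order and is excluded from golden comparisons.

## Synthetic-data generators

All generators take an explicit integer seed (numpy `default_rng`; no
global state) and are byte-deterministic given spec + seed.

* **Inventory** (`n = 613` default): independent categorical draws per
  field, with default proportions matching the compiled world inventory
  (36.5% woody / 11.7% vine / 50.9% herb; domestication shares 2.9 / 30.7 /
  61.0 / 1.5 / 2.6%(±); 18.5% grown as annuals). Published form shares sum
  to 0.991 from display rounding; draws renormalise. Each synthetic species
  carries one part and one climate, so multi-count and single-count
  breakdowns coincide — real species often carry several.
* **Composition** (`n = 240`, superabundance target 0.64 default):
  per-species latent concentrations are log-normal per nutrient (positive,
  right-skewed — a modelling convenience; nothing distributional is known
  about the real literature data). The common log-location shift is solved
  analytically from the log-normal tail so that
  `P(at least one nutrient > ref_max) = target` under independence
  (`scipy.optimize.brentq` on the closed-form expression), then verified by
  simulation in tests. Sources observe the latent value with mean-one
  multiplicative jitter (log-sd 0.10 default); dry-basis rows (20% default)
  carry a moisture fraction in [0.70, 0.95] encoded so conversion recovers
  the latent fresh value exactly. Not emulated: inter-nutrient correlation,
  per-nutrient missingness patterns, between-source systematic bias — so a
  passing calibration test shows the pipeline's arithmetic is right, not
  that real composition data behave log-normally.
* **Area series** (1967–2017 default): linear or exponential trend plus
  additive Gaussian noise, negative draws clamped to 0 with a warning.
  Real commodity-area series have autocorrelated, heteroscedastic
  deviations; the generator's white noise is enough to exercise the OLS
  sampling distribution, which is what the tests check.

Problem sizes in the test suite (613 species, 240-species cohorts, 100-seed
replicate loops, 10⁴ random classification cases) match the study's stated
dimensions; they run in seconds.

## Fixtures

`perveg.fixtures` carries the published golden values in machine-readable
form — rate entries, the class grid and back-derived reference ranges, the
12-scenario grid, the two multi-nutrient species lists with their printed
XH/VH/H labels, the five cultivated-area components, and the 22
reference-crop names — each row tagged with a provenance string. Tests only
assert published values; figure-only and supplementary-only quantities
(e.g. the per-cell superabundance proportions, the 154-of-240 count) are
exercised through property tests on synthetic cohorts instead.
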