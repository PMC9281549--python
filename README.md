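# opfe — indicators for the online takeaway food environment

`opfe` measures the *online public food environment for takeaway food*: the
set of food outlets on a food-delivery platform and the single-meal products
they sell. Traditional food-environment studies count outlets per area;
that treats a salad kitchen and a fried-chicken shop as equal exposures.
This package implements an indicator system that instead weights each
outlet by what it actually sells and how much of it is consumed, and then
compares the resulting spatial pattern with the counting method.

It is aimed at public-health and urban-food-environment researchers working
with platform (or platform-like) data: one row per meal with a set of
food-group labels, three binary unhealthy-food labels, and a monthly sales
count; one row per outlet with coordinates; subdistrict polygons in GeoJSON.

## The model

For meal *i* with monthly sales *Sᵢ*:

- **Healthy score** `lᵢ = 1[fried] + 1[sugar beverage] + 1[high-salt
  sauce/pickle]`, so `0 ≤ lᵢ ≤ 3`; `lᵢ = 0` defines a healthy meal.
- **Dietary diversity score** `DDSᵢ` = number of distinct food groups in
  the meal (12-group registry). Because higher DDS means a *better* meal,
  the unhealthy-impact indicators use the normalized reciprocal
  `r̄ᵢ = (1/DDSᵢ) / max_k(1/DDS_k)` (computed over the whole analysis set);
  the healthy indicator uses the normalized DDS `d̄ᵢ = DDSᵢ / max_k DDS_k`.

For an outlet with meals *i = 1…n*:

- **Health weight** `W = N_h / N_t`, the share of its meals with `lᵢ = 0`.
  `W = 1` defines a healthy outlet, `W < 1` an unhealthy one.
- **TUHII** `= Σ lᵢ · r̄ᵢ · Sᵢ` — total unhealthy impact (all outlets).
- **HII** `= Σ d̄ᵢ · Sᵢ` — impact of a healthy outlet (only when `W = 1`).
- **UHII** `= Σ r̄ᵢ · Sᵢ` — impact of an unhealthy outlet (only when
  `W < 1`; note there is no `lᵢ` factor, so the outlet's healthy meals
  still contribute).

Outlets and meals are classified by a two-level taxonomy (3 Level I /
14 Level II categories) with deterministic tie-breaking rules; indicators
are Z-standardized (TUHII over all outlets, HII within healthy, UHII
within unhealthy outlets) and quartile-labelled; spatial structure is
tested with Global Moran's I under inverse-distance weights, mapped with a
weighted quartic-kernel density at 30 m resolution, aggregated into
subdistrict polygons, and compared with outlet counts via Spearman
correlation. See `docs/methods.md` for details and design choices.

## Worked example

```python
import opfe

# one meal with every unhealthy label, one with none
meal = opfe.MealRecord("o1", "m1", ("1-3",),
                       frozenset({"cereals", "vegetables", "eggs"}),
                       fried=True, sugar_beverage=True, high_salt=True,
                       monthly_sales=40)
opfe.healthy_score(meal)        # -> 3   (the unhealthiest possible meal)
opfe.dds(meal)                  # -> 3   (three distinct food groups)

# an outlet's health weight from its meals' scores
opfe.health_weight([0, 0, 1, 2])  # -> 0.5

# end-to-end on a seeded synthetic dataset (400 outlets, ~9,700 meals)
from opfe.pipeline import PipelineConfig, run_pipeline
from opfe.synthetic import default_paperlike_config

res = run_pipeline(PipelineConfig(
    synthetic=default_paperlike_config(seed=3, n_outlets=400),
    output_dir="opfe_output", seed=3))
res["manifest"]["counts"]
# {'meals_in': 9674, 'meals_retained': 9674, 'meals_excluded': 0,
#  'row_errors': 0, 'outlets': 400, 'healthy_outlets': 53,
#  'unhealthy_outlets': 347, 'polygons': 9}
res["indicators"].groupby("category")["z_TUHII"].mean().round(3)
# category        (1-7 = western fast-food leads the unhealthy impact;
# 1-1    0.213     1-8 = healthy light recipes is lowest)
# 1-2   -0.302
# 1-3   -0.159
# 1-7    2.352
# 1-8   -0.560
# 3-1    0.151
```

The same pipeline runs from the shell: `opfe run-all --seed 3 --n-outlets
400 --out opfe_output` (or on real files via `--meals/--outlets/
--polygons`). Outputs: `outlet_indicators.csv`, `polygon_summary.csv`,
`kde_*.asc` rasters, `method_comparison.csv` and a run `manifest.json`.

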