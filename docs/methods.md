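# Methods

## The indicator system

The package measures a takeaway food environment at three levels.

**Meals.** Each single-meal product carries three binary unhealthy-food
labels — fried food, sweetened sugar beverage, high-salt sauce or pickle —
assigned upstream by human interpretation of photos and names (or by the
synthetic generator). The healthy score `l` is their sum; `l = 0` defines a
healthy meal. Missing labels raise an error rather than being imputed as 0,
because silent imputation biases `l` (and hence every downstream indicator)
toward "healthy". The dietary diversity score `DDS` counts distinct food
groups out of a 12-group registry (cereals; roots and tubers; vegetables;
mushrooms and edible algae; meat, poultry and offal; eggs; fish and
seafood; pulses and legumes; nuts; dairy; fruits; miscellaneous). `DDS` is
undefined for a meal with no food groups, which is rejected at the schema
boundary.

**Normalization of DDS.** The impact indicators need a per-meal weight
that *increases* as diversity falls, so they use the reciprocal `1/DDS`,
rescaled over the entire post-filter analysis set (not per outlet, so
outlets stay comparable). The default scheme divides by the largest
reciprocal present, mapping the least diverse meal to 1 and keeping every
weight in (0, 1]. A min–max alternative (`scheme="minmax"`) is provided for
sensitivity analysis but is not the default: it maps the most diverse
meal's weight to exactly 0, deleting that meal's sales from the impact
sums, which is a modelling artifact rather than a statement about the
meal. The healthy-outlet indicator uses the analogously max-scaled `DDS`
itself.

**Outlets.** Health weight `W` is the share of an outlet's meals with
`l = 0`; `W = 1` splits outlets into a healthy and an unhealthy group.
Three sales-weighted sums follow: TUHII (over all outlets,
`Σ l·r̄·S`), HII (healthy outlets, `Σ d̄·S`) and UHII (unhealthy
outlets, `Σ r̄·S`). UHII deliberately has no `l` factor — an unhealthy
outlet's healthy meals still contribute — which surprises users but
follows the indicator's definition: UHII measures the reach of an outlet
that sells *any* unhealthy food, not the unhealthy fraction of its menu.

## Classification rules

Meals: (1) items from a single Level II category decide directly; (2) when
Level I groups tie in item count, Level I code 1 (Meal) takes priority and
the modal Level II code within the winning group decides; (3) otherwise
the overall modal Level II code decides. "The same or similar quantities"
is operationalized as exactly equal counts by default with a configurable
relative tolerance (`level1_tolerance`, default 0), since no quantitative
definition of "similar" exists. Modal ties inside rules 2–3 break to the
smallest code string — deterministic and documented, nothing more.

Outlets take the modal category of their meals, subject to a dominance
check: the max/min ratio of category counts (MMR) must reach a cutoff,
default 1.5. The cutoff is provisional (the originating definition is not
public) and exposed in configuration; a modal tie or failed dominance
yields Unknown (`3-1`). Classification counts item/meal occurrences, never
grams — weights play no role in any rule.

## Statistics

- **Z-standardization** uses the sample (n−1) standard deviation. TUHII is
  standardized across all outlets; HII within the healthy subset; UHII
  within the unhealthy subset, matching the separate group analyses.
- **Quartile labels** use linear-interpolation sample quantiles
  (configurable in principle via numpy; the boundary chain is
  lower-closed: top group `≥ 75% quantile`, then `[median, 75%)`,
  `[25%, median)`, `< 25%`). Constant input collapses every label to the
  top group and emits a warning.
- **Group differences**: Levene's test centered at the mean decides
  homoscedasticity at 0.05; the classic one-way ANOVA runs when variances
  are homogeneous, Welch's ANOVA otherwise. Groups with fewer than two
  observations are dropped with a warning.
- **Global Moran's I** uses inverse-distance weights `w_ij = 1/d_ij^p`
  (p = 1, no cutoff by default; both configurable), zero diagonal, with
  coincident points floored at 15 m (half the default raster cell) to keep
  weights finite. `E[I] = −1/(n−1)`; significance comes from the
  randomization-variance normal approximation by default, with a seeded
  999-permutation alternative.
- **Kernel density** uses the planar quartic kernel
  `K(d) = 3/(πh²)(1 − d²/h²)²` for `d < h`, which integrates to one, so
  the surface mass equals the summed point weights up to discretization.
  Cell size defaults to 30 m; the default bandwidth is a Silverman-style
  rule `1.06·σ·n^(−1/5)` on the projected coordinates (the resolution is
  part of the method; the bandwidth is not, so it is exposed). Rasters are
  written as plain-text ESRI ASCII grids.
- **Geometry** is planar. Lon/lat inputs are projected with a local
  equirectangular projection about the data centroid — at city scale
  (tens of km) the distance error is far below the 30 m cell. Boundary
  points in the polygon join go to the first matching polygon in file
  order; points outside every polygon land in an `unassigned` bucket with
  a warning, so totals are always conserved.
- **Method comparison**: Spearman rank correlation between per-polygon
  outlet counts (all / healthy / unhealthy) and per-polygon sums of the
  corresponding standardized indicator, with scipy's exact/t-approximation
  p-value policy.

## Synthetic data

The generator emulates the structure the indicators assume, not any real
platform's distributions. Outlets of six types (ST staple, ND noodles and
dumplings, SET set meal, WFF western fast-food, HLR healthy light recipes,
UN mixed-menu) are placed uniformly in a grid of square polygons
(default 3×3 at 2 km). Per type, meals draw: the three unhealthy labels as
independent Bernoullis; a food-group count `1 + Binomial(11, (μ−1)/11)`
(expectation μ, support 1–12) with type-biased group membership (HLR
favours vegetables/fruits, ST cereals, WFF meat/dairy); log-normal monthly
sales. The default parameters order expected healthy score
HLR < ND < overall < ST < WFF and expected DDS
ST < ND < overall < WFF < HLR, with WFF carrying the heaviest sales
(`sales_mu` 4.2 vs ≈3.1 elsewhere) — the qualitative pattern the method is
meant to expose. A type-specific share of outlets (45% HLR down to 5% WFF,
≈15% overall) sells only healthy meals, because a fully-healthy outlet
group (`W = 1`) is a structural feature of real data that per-meal
Bernoulli labels alone almost never produce at realistic menu sizes.

What the generator does **not** emulate: real menu text and photo
interpretation noise, spatial clustering of outlets along streets,
correlation between sales and location, platform ranking effects, and any
fitted match to real per-type distributions. Passing tests therefore show
the pipeline recovers planted structure of this kind, not that the
indicator is validated on real data.

The planted-cluster study places a centre polygon (3×3 grid of 1 km cells,
300 outlets) whose outlets are 85% WFF / 15% ST, and asks whether the
maximum of the UHII density surface (30 m cells, 300 m bandwidth) falls in
that polygon. The bandwidth is fixed rather than rule-based because the
detection question is about a known 1 km feature.

Replicate studies (`opfe.validation`) run 20 seeded replicates at 800
outlets for the ordering checks and 50 replicates at 300 outlets for
cluster detection; these sizes keep a full run around a minute on one core
while leaving the binomial noise on each check well below the margins
being tested.

## Record exclusion

Filtering is flag-driven: ten exclusion rules (sauce ingredients, separate
beverages, concomitant food, pot/fried-BBQ/seafood categories,
multi-person meals, separate dishes, delicatessen items, single soups,
non-meal snacks, unrecognizable items) arrive as codes i–x on each record,
set by the upstream interpreter or the generator. A dropped record is
attributed to exactly one rule — the first active flag in i–x order — or
to the category restriction (only ST, ND, SET, WFF, HLR meals enter the
analysis). The pipeline manifest reports counts per rule, and
`meals_in = meals_retained + meals_excluded` always holds.

## Numerical and degenerate-input policy

Errors are typed: invalid inputs (empty compositions, unknown codes,
missing labels), state errors (indicator sums before normalization),
degenerate inputs (constant vectors for Z-scores/Moran/Spearman, < 4
values for quartiles, coincident point sets) and schema errors (strict 0/1
boolean parsing, line-numbered row reports). Vectorized indicator sums are
plain floating-point dot products; they match per-meal Python loops to
1e-9 in the test suite, and Moran's I matches an independent double-loop
evaluation to 1e-10.

## Known limitations

- The three binary labels are proxies; no oil/salt/sugar quantities are
  estimated, and the healthy score cannot rank two fried meals.
- DDS treats all food groups equally; a meal of cereals+nuts scores like
  vegetables+fish.
- The equirectangular projection is inappropriate for study areas spanning
  several degrees of latitude; supply projected coordinates instead.
- The MMR cutoff default (1.5) is provisional; outlet categories near the
  cutoff should be treated as sensitive to it.
- Moran's I significance assumes the randomization moments are adequate;
  for n < ~30 prefer the permutation option.
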