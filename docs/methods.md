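# Methods

## The problem

Sustainability standards for oil palm — RSPO, RSB and the EU renewable
energy directive, together with the High Conservation Value (HCV)
toolkits they reference — define criteria under which land conversion
is considered non-compliant: formally protected areas, ranges and
habitats of protected species, intact forest landscapes, hydrological
and erosion-control functions, carbon stocks, community provisioning
and customary rights, and the crop's own biophysical requirements.
`palmrisk` turns those criteria into a spatially explicit desk-study
pipeline: each criterion becomes a raster indicator layer classified
into four ordinal risk classes, the layers are combined into a single
Risk Indicator Map (RIM), and the RIM is cross-tabulated against
concession and land-use-plan zones to rank where expansion carries the
lowest risk of violating the standards.

## Risk classes and rule tables

Risk of non-compliance is ordinal:

    LOW (0) < MEDIUM (1) < HIGH (2) < VERY_HIGH (3)

`VERY_HIGH` is equivalent to "unsuitable" in the standards' wording;
the parser accepts both labels.  `NODATA` marks missing input and is
deliberately unranked — comparing it raises, and classification maps
missing values to `NODATA`, never silently to `LOW`.

Each indicator has a rule table: for continuous indicators an ordered
list of value intervals with *explicit* open/closed endpoints, for
categorical indicators disjoint sets of named classes.  The shipped
default registry holds 17 tables spanning three principles
(conservation values; human wellbeing and land rights; biophysical
suitability).  Key continuous defaults:

| indicator | units | LOW | MEDIUM | HIGH | VERY_HIGH |
|---|---|---|---|---|---|
| rainfall (3.1.1) | mm/yr | [1750, 5000] | [1500, 1750) | [1250, 1500) | [0, 1250) ∪ (5000, ∞) |
| slope (3.2.1) | % | [0, 8] | (8, 15] | (15, 30] | (30, ∞) |
| elevation (3.2.2) | m | [0, 200] | (200, 500] | (500, 1000] | (1000, ∞) |
| erosion (1.2.2, 3.3.4) | t/ha/yr | [0, 15] | (15, 60] | (60, 180] | (180, ∞) |
| carbon stock (1.2.4) | t/ha | [0, 60] | (60, 70] | (70, 80] | (80, ∞) |
| soil depth (3.3.3) | cm | [100, ∞) | [75, 100) | [50, 75) | [0, 50) |

Design choices that were genuinely open:

* **Boundary convention.** Printed threshold tables use touching bands
  ("8–15 %", "15–30 %") without saying where the boundary belongs.  We
  close every shared boundary on the *less risky* side: slope exactly
  15 % is MEDIUM, rainfall exactly 1750 mm is LOW, carbon exactly
  80 t/ha is HIGH.  One consistent rule, and conservative in the sense
  that land is only reported usable when the printed low-risk band
  actually contains the value.
* **Two-sided rainfall band.** The unsuitable class is both "too dry"
  (< 1250 mm) and "too wet" (> 5000 mm); it is encoded as a union of
  two intervals, not one range.
* **Shared erosion thresholds.** Indicators 1.2.2 (ecosystem-service
  erosion risk) and 3.3.4 (soil erosion risk) carry identical
  thresholds; the registry encodes them once and lets both ids
  reference the same rule list, preserving the indicator hierarchy.
* **Three-class tables.** 1.1.1 has no HIGH band and 1.2.3 no MEDIUM
  band (no threshold exists for those classes in the standards); the
  tables simply never emit the class, and the validator accepts
  3-class partitions.
* **Categorical matching** is exact and case-insensitive on normalized
  whitespace.  Community-use (2.1.1), customary-rights (2.2.2),
  hydrology (1.2.1) and fire (1.2.3) tables store the standards'
  qualitative classes as opaque category strings; their field
  operationalization is out of scope.  Where the standards mention
  cultural sites at two levels, the category string is assigned to the
  higher (VERY_HIGH) band.
* An **unknown category** falls to the table's default class (LOW for
  the shipped tables, i.e. "no overlap") with a logged warning; a
  continuous value outside the declared domain yields NODATA with a
  warning.  Validation (`validate_rule_table`) never raises — it
  reports gaps and overlaps, and an empty report is the partition
  certificate the test suite asserts for every shipped table.

## Geometric layers

Three indicators need geometry beyond cell-wise classification:

* **Formal protection (1.1.1):** protected polygons rasterized by the
  cell-center rule → VERY_HIGH; a 1 km buffer ring → MEDIUM; else LOW.
* **Species (1.1.2):** per-cell maximum of distribution (MEDIUM),
  habitat (HIGH), and breeding/nesting or other critical sites
  (VERY_HIGH).
* **Intact forest / ecosystems (1.1.3):** connected forest blocks
  strictly larger than 20 000 ha, plus a 3 km buffer, → MEDIUM;
  ≥ 2 ecotone regions or endangered ecosystems → HIGH; rare
  ecosystems (karst class 1, peat, freshwater swamp, mangrove, heath
  forest, cloud forest) → VERY_HIGH; per-cell maximum.

Numerical conventions: buffers use exact Euclidean distance transforms
between cell centers (scipy's EDT) with a 1e-9 relative tolerance at
the radius so exact hits are included; forest blocks are 8-connected
by default (diagonal continuity should not split a block), with
4-connectivity available; the 20 000 ha threshold is strict, and block
area is measured *before* buffering — the ring inherits MEDIUM but
never lifts a block over the threshold.  Whether the original study's
buffers were Euclidean or legal offsets is unstated; Euclidean is the
documented choice here.

## The overlay

Layers are combined by Liebig's law of the minimum applied to
suitability: the cell's combined class is the maximum risk rank across
layers.  The operation is commutative, associative and idempotent in
the layer list, which the property tests exercise.  Consequences used
as invariants: the combined LOW region is exactly the intersection of
the per-layer LOW regions (absent NODATA), so the combined LOW area
can never exceed the smallest per-layer LOW area, and adding a layer
can only shrink it.

NODATA policy defaults to `ignore` (a cell is NODATA only if all
layers miss it): the reference case study's layers evidently had
unequal coverage — their printed row totals differ by ~2 % — yet every
cell received a combined class.  `propagate` (any missing layer blanks
the cell) is available for strict analyses.

## Tabulation and ranking

Areas are cell counts × cell area (ha); the CRS is assumed projected
and equal-area, which the tools verify only in the sense of refusing
mixed CRS declarations — there is no reprojection engine.  Percentages
are rounded half-up to integers.  Per-layer and combined-map rows use
their own row total as denominator; zonal rows (RIM × concessions,
RIM × land-use plan) use the whole mapped area, which is the published
tabulation's convention and keeps zone shares comparable.

Expansion options are ranked by legal practicability: low-risk land in
*inactive* concessions first (licenses already under application), then
low-risk land outside existing concessions by land-use-plan class in
the fixed order other use (APL) > conversion forest (HPK) > production
forest (HP/HPT) > protection forest.  Indicator weighting is
deliberately out of scope (the standards provide none); so are cost
surfaces and placement optimization.

The published combined map prints zero MEDIUM hectares even though
several input layers contain MEDIUM.  Under a pure per-cell maximum
that happens only if every MEDIUM cell is overruled elsewhere; whether
the original analysis additionally collapsed MEDIUM is unknowable from
the printed record.  This package implements the pure maximum and the
report flags the situation either way.

## Synthetic landscapes

No input rasters are distributable, so the generator emulates a
province statistically: per-indicator class *marginals* (defaulting to
the published West Kalimantan shares, e.g. LOW = 79 % for 1.1.1 down
to 37 % for 1.2.1) and a spatial autocorrelation scale.  Fields are
Gaussian white noise convolved with a moving-average kernel of
half-width equal to the correlation length in cells (3 by default,
i.e. 300 m at the default 100 m resolution — the scale is a free
parameter, as the source record carries no correlogram information),
standardized, and quantile-sliced so realized class counts hit the
targets within one cell.  Continuous indicators are then mapped into
concrete values inside the matching rule-table band (kept 2 % off the
band edges so boundary conventions cannot flip a class); categorical
indicators become integer-coded mosaics with one representative
category per class.  Open-ended top bands are capped at 1.5 × the
band's lower bound + 100 units when drawing representative values.

Polygon layers (protected areas, active/inactive concessions) are
random star-shaped polygons with exact areas drawn from configurable
ranges; land-use-plan zones are a quantile-sliced correlated field
with shares (0.35, 0.15, 0.30, 0.20) across APL/HPK/HP-HPT/protection
— plausible round numbers chosen once, since the source record prints
no land-use-plan marginals.

What the generator does **not** emulate: the real province's
geography, cross-indicator correlation (layers are independent draws),
coastline/nodata structure, or multi-scale anisotropic autocorrelation.
Passing tests therefore demonstrate the *pipeline's* correctness and
the arithmetic consequences of the overlay (e.g. the independent-layer
product law for the combined LOW share), not fidelity to any real
landscape.  Default desk-scale problem size is 200×200 cells of 1 ha;
tests and the acceptance script use 100×100 where a marginal or a
distributional law is being measured.

## I/O

Rasters are exchanged as ESRI ASCII grids (plain text) with a JSON
sidecar carrying the CRS identifier and dtype; class rasters are
rank-encoded uint8 (0–3, 255 = nodata).  Polygons are GeoJSON.  All
outputs (CSV, markdown report, rasters) are pure functions of inputs,
configuration and seed; reruns are byte-identical, which the
acceptance suite checks end-to-end.

## Known limitations

* No reprojection; all inputs must share a projected, equal-area CRS.
* No derivation of land cover from imagery, no field HCV/FPIC
  procedures, no greenhouse-gas life-cycle accounting — those precede
  or follow this pipeline.
* Qualitative criteria are only as good as the categorical masks
  supplied for them.
* The published hectare figures themselves derive from proprietary
  provincial GIS layers and cannot be reproduced from raw data here;
  what is reproduced is their internal arithmetic and every structural
  property of the method.
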