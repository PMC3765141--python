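# palmrisk

Spatially explicit identification of low-risk ("degraded") land for
sustainable oil palm expansion.

Certification standards for palm oil (RSPO, RSB, the EU renewable
energy directive) and the High Conservation Value toolkits define
criteria that make land unsuitable for conversion: protected areas,
species habitats, intact forest, hydrological and erosion functions,
carbon stocks, community use and customary rights, and the crop's
biophysical needs.  `palmrisk` is a desk-study pipeline for land-use
planners and conservation analysts that makes those criteria spatially
explicit:

1. **Classify** — each indicator raster is mapped through a rule table
   into ordinal risk classes `LOW < MEDIUM < HIGH < VERY_HIGH`
   (17 default tables ship with the package; thresholds like rainfall
   1750–5000 mm/yr = LOW or carbon stock > 80 t/ha = VERY_HIGH).
   Indicators that need geometry — 1 km buffers around protected
   areas, contiguous forest blocks > 20 000 ha plus a 3 km buffer,
   tiered species ranges — have dedicated builders.
2. **Combine** — layers are overlaid by Liebig's law of the minimum
   applied to suitability: a cell's combined class is the *worst*
   class among its layers,
   `RIM(x) = max_i class_i(x)`,
   because one violated criterion suffices for non-compliance.  The
   result is the Risk Indicator Map (RIM).
3. **Report** — the RIM is tabulated (hectares and integer percentage
   shares per class), cross-tabulated against concession status and
   provincial land-use-plan zones, and turned into a ranked list of
   expansion options: low-risk land in inactive concessions first,
   then low-risk land outside concessions in the legal order
   other use (APL) > conversion forest (HPK) > production forest
   (HP/HPT) > protection forest.

A synthetic-landscape generator (correlated random fields quantile-
sliced to prescribed class proportions, random concession and zone
polygons) makes every stage testable without proprietary GIS data; its
defaults reproduce the per-layer class marginals of the published
West Kalimantan case study, which also ships as reference data.

## Worked example

```
palmrisk simulate --seed 42 --out run/bundle
palmrisk classify --bundle run/bundle --out run/classes
palmrisk combine  --classified run/classes --out run/rim
palmrisk report   --bundle run/bundle --classified run/classes \
                  --rim run/rim/rim.asc --out run/report
```

`run/report/report.md` then contains (seed 42, 200×200 cells of 1 ha,
default marginals):

```
| layer | low ha | medium ha | high ha | very high ha | low % | medium % | high % | very high % |
|---|---|---|---|---|---|---|---|---|
| 1.1.1 | 31636 | 528 | 0 | 7836 | 79 | 1 | 0 | 20 |
| 1.1.2 | 24664 | 0 | 15336 | 0 | 62 | 0 | 38 | 0 |
| 1.1.3 | 18705 | 4636 | 12388 | 4271 | 47 | 12 | 31 | 11 |
| 1.2.1 | 14792 | 23805 | 929 | 474 | 37 | 60 | 2 | 1 |
| 1.2.2 | 26691 | 9627 | 2466 | 1216 | 67 | 24 | 6 | 3 |
| 1.2.4 | 25467 | 0 | 8291 | 6242 | 64 | 0 | 21 | 16 |
| 3.1.1 | 22300 | 32 | 1799 | 15869 | 56 | 0 | 4 | 40 |
| RIM | 743 | 2766 | 10659 | 25832 | 2 | 7 | 27 | 65 |
```

Each indicator row reproduces its requested class shares (here the
published case-study marginals: 79 % of the area is clear of protected
areas, 37 % clear of hydrological constraints, …).  The combined RIM
row shows the overlay's bite: only 2 % of this synthetic province is
low-risk under *all* criteria simultaneously — with independently drawn
layers the combined LOW share converges to the product of the per-layer
LOW shares (0.79 × 0.62 × 0.47 × 0.37 × 0.67 × 0.64 × 0.56 ≈ 0.02).
The report further lists per-zone tables and the ranked low-risk
hectares per legal class.

The same steps run on real data by placing `indicator_<id>.asc`
rasters, zone rasters and a `manifest.yaml` in a bundle directory;
`--rules` accepts a custom rule-registry YAML (see
`src/palmrisk/data/default_rules.yaml` for the schema).

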