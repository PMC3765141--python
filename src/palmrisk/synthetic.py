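"""Synthetic province-like input bundles.

No dataset is distributed with the original case study, so every
pipeline stage is exercised on synthetic landscapes instead: spatially
autocorrelated random fields quantile-sliced to prescribed risk-class
proportions, plus random polygon sets for protected areas, concessions
and land-use-plan zones.

The generator's default per-indicator class proportions are the
published West Kalimantan marginals (see :mod:`palmrisk.reference`),
so a default scenario statistically resembles the case-study province
at desk scale (default 200x200 cells of 1 ha).  Only the marginal
class shares and an autocorrelation scale are emulated — not the
actual geography, nor cross-indicator correlation (layers are drawn
independently unless they share a field).

Fields are smoothed white noise: Gaussian noise convolved with a
moving-average (uniform) kernel whose half-width is the requested
correlation length, then standardized.  Correlation length 0 is plain
white noise.  Everything is deterministic under the scenario seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from shapely import affinity
from shapely.geometry import Polygon

from .grid import CLASS_NODATA, Grid, VectorLayer, write_ascii_grid, write_geojson
from .overlay import LEGAL_PRIORITY, ZoneMap
from .rules import RISK_CLASSES, RiskClass, RuleRegistry, RuleTable, load_rule_registry
from . import reference

#: Indicators drawn as continuous value fields (classified downstream by
#: their rule tables); the rest of the seven are categorical mosaics.
CONTINUOUS_INDICATORS = ("1.2.2", "1.2.4", "3.1.1")
CATEGORICAL_INDICATORS = ("1.1.1", "1.1.2", "1.1.3", "1.2.1")


def default_indicator_proportions() -> dict[str, tuple[float, float, float, float]]:
    """Per-indicator class shares normalized from the published marginals."""
    df = reference.load_west_kalimantan_reference()
    out = {}
    for ind in reference.INDICATOR_ROWS:
        areas = np.array(
            [df.loc[ind, f"{c}_ha"] for c in ("low", "medium", "high", "very_high")],
            dtype=float,
        )
        out[ind] = tuple(areas / areas.sum())
    return out


def correlated_field(
    rows: int, cols: int, correlation_length_cells: float, seed
) -> np.ndarray:
    """Zero-mean unit-variance random field with tunable autocorrelation."""
    if rows <= 0 or cols <= 0:
        raise ValueError("field dimensions must be positive")
    if correlation_length_cells < 0:
        raise ValueError("correlation length must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((rows, cols))
    half = int(round(correlation_length_cells))
    if half > 0:
        noise = ndimage.uniform_filter(noise, size=2 * half + 1, mode="reflect")
    noise = noise - noise.mean()
    sd = noise.std()
    if sd > 0:
        noise = noise / sd
    return noise


def field_to_classes(field: np.ndarray, proportions) -> np.ndarray:
    """Quantile-slice a real field into rank-encoded risk classes.

    Thresholds sit at the empirical quantiles of the field, so realized
    class counts match the targets to within one cell; the monotone
    transform preserves the field's spatial structure.
    """
    p = np.asarray(proportions, dtype=float)
    if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be 4 non-negative values summing to 1")
    flat = np.asarray(field, dtype=float).ravel()
    n = flat.size
    if np.ptp(flat) == 0 and np.count_nonzero(p) > 1:
        raise ValueError("constant field cannot be split into multiple classes")
    order = np.argsort(flat, kind="stable")
    bounds = np.round(np.cumsum(p) * n).astype(int)
    ranks = np.empty(n, dtype=np.uint8)
    start = 0
    for cls, stop in zip(RISK_CLASSES, bounds):
        ranks[order[start:stop]] = cls.rank
        start = stop
    ranks[order[start:]] = RiskClass.VERY_HIGH.rank  # rounding remainder
    return ranks.reshape(np.asarray(field).shape)


def random_polygons(n: int, size_range_ha, extent, seed) -> list[Polygon]:
    """Random simple (star-shaped) polygons with exact areas in range.

    ``extent`` is (xmin, ymin, xmax, ymax) in map metres; polygon areas
    are drawn uniformly from ``size_range_ha`` and made exact by
    similarity scaling.  Polygons are clamped to lie inside the extent.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = extent
    lo_ha, hi_ha = size_range_ha
    polys: list[Polygon] = []
    for _ in range(n):
        target_m2 = rng.uniform(lo_ha, hi_ha) * 10_000.0
        k = int(rng.integers(10, 20))
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=k))
        radii = 1.0 + 0.5 * rng.uniform(-1, 1, size=k)
        ring = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
        poly = Polygon(ring)
        s = float(np.sqrt(target_m2 / poly.area))
        poly = affinity.scale(poly, xfact=s, yfact=s, origin=(0, 0))
        bx_min, by_min, bx_max, by_max = poly.bounds
        w, h = bx_max - bx_min, by_max - by_min
        cx = rng.uniform(xmin, max(xmin, xmax - w))
        cy = rng.uniform(ymin, max(ymin, ymax - h))
        polys.append(affinity.translate(poly, xoff=cx - bx_min, yoff=cy - by_min))
    return polys


def _interval_for_class(table: RuleTable, cls: RiskClass) -> tuple[float, float]:
    """A finite value range producing the given class under the table."""
    for rule in table.rules:
        if rule.risk is cls:
            lo, hi = rule.interval.lower, rule.interval.upper
            if not np.isfinite(hi):
                hi = lo * 1.5 + 100.0  # representative cap for open-ended bands
            return lo, hi
    raise ValueError(f"table {table.indicator_id} never emits {cls.name}")


def _values_from_classes(
    field: np.ndarray, ranks: np.ndarray, table: RuleTable
) -> np.ndarray:
    """Map the field into concrete indicator values whose rule-table class
    equals the quantile class, preserving within-class ordering."""
    values = np.empty(field.shape, dtype=float)
    flat_f, flat_r = field.ravel(), ranks.ravel()
    out = values.ravel()
    for cls in RISK_CLASSES:
        idx = np.nonzero(flat_r == cls.rank)[0]
        if idx.size == 0:
            continue
        lo, hi = _interval_for_class(table, cls)
        # within-class quantile, kept off the endpoints so open/closed
        # boundary conventions cannot flip the class
        u = (np.argsort(np.argsort(flat_f[idx])) + 0.5) / idx.size
        out[idx] = lo + (0.02 + 0.96 * u) * (hi - lo)
    return values


@dataclass
class SyntheticScenario:
    """Specification of one synthetic input bundle."""

    n_rows: int = 200
    n_cols: int = 200
    cell_size_m: float = 100.0
    seed: int = 0
    correlation_length_cells: float = 3.0
    #: indicator id -> (low, medium, high, very_high) target shares;
    #: defaults to the published case-study marginals.
    indicator_proportions: dict[str, tuple] = dc_field(default_factory=dict)
    #: land-use-plan class shares in LEGAL_PRIORITY order
    land_use_plan_proportions: tuple = (0.35, 0.15, 0.30, 0.20)
    n_protected_areas: int = 5
    protected_area_size_ha: tuple = (300.0, 1500.0)
    n_active_concessions: int = 5
    n_inactive_concessions: int = 5
    concession_size_ha: tuple = (500.0, 2000.0)
    crs_id: str = "EPSG:32749"

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("scenario dimensions must be positive")
        if self.cell_size_m <= 0:
            raise ValueError("cell size must be positive")
        props = dict(default_indicator_proportions())
        props.update(self.indicator_proportions)
        for ind, p in props.items():
            arr = np.asarray(p, dtype=float)
            if arr.shape != (4,) or (arr < 0).any() or abs(arr.sum() - 1) > 1e-9:
                raise ValueError(f"invalid proportions for indicator {ind}")
        self.indicator_proportions = {k: tuple(v) for k, v in props.items()}
        lup = np.asarray(self.land_use_plan_proportions, dtype=float)
        if lup.shape != (4,) or (lup < 0).any() or abs(lup.sum() - 1) > 1e-9:
            raise ValueError("invalid land-use-plan proportions")

    def to_doc(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "cell_size_m": self.cell_size_m,
            "seed": self.seed,
            "correlation_length_cells": self.correlation_length_cells,
            "indicator_proportions": {
                k: [float(x) for x in v]
                for k, v in sorted(self.indicator_proportions.items())
            },
            "land_use_plan_proportions": [
                float(x) for x in self.land_use_plan_proportions
            ],
            "n_protected_areas": self.n_protected_areas,
            "protected_area_size_ha": list(self.protected_area_size_ha),
            "n_active_concessions": self.n_active_concessions,
            "n_inactive_concessions": self.n_inactive_concessions,
            "concession_size_ha": list(self.concession_size_ha),
            "crs_id": self.crs_id,
        }

    @classmethod
    def from_doc(cls, doc: dict) -> "SyntheticScenario":
        doc = dict(doc)
        if "indicator_proportions" in doc:
            doc["indicator_proportions"] = {
                k: tuple(v) for k, v in doc["indicator_proportions"].items()
            }
        for key in ("land_use_plan_proportions", "protected_area_size_ha",
                    "concession_size_ha"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass
class ScenarioBundle:
    """Grid-congruent inputs for one full pipeline run."""

    scenario: SyntheticScenario
    #: indicator id -> raw value raster (float for continuous indicators,
    #: integer category codes for categorical ones)
    indicator_values: dict[str, Grid]
    #: indicator id -> code->category-name mapping (categorical only)
    categories: dict[str, dict[int, str]]
    protected_areas: VectorLayer
    concession_polygons: VectorLayer
    land_use_plan: ZoneMap
    concessions: ZoneMap

    def manifest(self) -> dict:
        return {
            "scenario": self.scenario.to_doc(),
            "categories": {k: dict(v) for k, v in sorted(self.categories.items())},
            "land_use_plan_zones": dict(self.land_use_plan.zones),
            "concession_zones": dict(self.concessions.zones),
        }


def _representative_categories(table: RuleTable) -> dict[int, str]:
    """One category name per emitted class, keyed by class rank."""
    cats = {}
    for rule in table.rules:
        if rule.categories:
            cats[rule.risk.rank] = sorted(rule.categories)[0]
    return cats


def generate_scenario(
    spec: SyntheticScenario, registry: RuleRegistry | None = None
) -> ScenarioBundle:
    """Draw a complete, grid-congruent synthetic input bundle."""
    if registry is None:
        registry = load_rule_registry()
    ss = np.random.SeedSequence(spec.seed)
    # fixed spawn order => determinism regardless of dict iteration
    names = (
        [f"field:{i}" for i in sorted(spec.indicator_proportions)]
        + ["lup", "protected", "concessions"]
    )
    children = dict(zip(names, ss.spawn(len(names))))

    template = Grid(
        cells=np.zeros((spec.n_rows, spec.n_cols)),
        x_origin=0.0,
        y_origin=spec.n_rows * spec.cell_size_m,
        cell_size=spec.cell_size_m,
        crs_id=spec.crs_id,
    )
    extent = (0.0, 0.0, spec.n_cols * spec.cell_size_m, spec.n_rows * spec.cell_size_m)

    indicator_values: dict[str, Grid] = {}
    categories: dict[str, dict[int, str]] = {}
    for ind in sorted(spec.indicator_proportions):
        fld = correlated_field(
            spec.n_rows, spec.n_cols, spec.correlation_length_cells,
            children[f"field:{ind}"],
        )
        ranks = field_to_classes(fld, spec.indicator_proportions[ind])
        table = registry[ind]
        if table.kind == "continuous":
            values = _values_from_classes(fld, ranks, table)
            indicator_values[ind] = template.like(values, nodata=None)
        else:
            cats = _representative_categories(table)
            missing = {
                RISK_CLASSES[i].name
                for i, p in enumerate(spec.indicator_proportions[ind])
                if p > 0 and i not in cats
            }
            if missing:
                raise ValueError(
                    f"indicator {ind}: nonzero share requested for class(es) "
                    f"{sorted(missing)} that its rule table never emits"
                )
            indicator_values[ind] = template.like(
                ranks.astype(np.int16), nodata=None
            )
            categories[ind] = cats

    lup_field = correlated_field(
        spec.n_rows, spec.n_cols, spec.correlation_length_cells, children["lup"]
    )
    lup_codes = field_to_classes(lup_field, spec.land_use_plan_proportions)
    land_use_plan = ZoneMap(
        grid=template.like(lup_codes.astype(np.int16) + 1, nodata=None),
        zones={i + 1: lab for i, lab in enumerate(LEGAL_PRIORITY)},
    )

    protected_polys = random_polygons(
        spec.n_protected_areas, spec.protected_area_size_ha, extent,
        children["protected"],
    )
    protected_areas = VectorLayer(
        protected_polys,
        [{"category": "national conservation area"} for _ in protected_polys],
        crs_id=spec.crs_id,
    )

    conc_ss = children["concessions"].spawn(2)
    active = random_polygons(
        spec.n_active_concessions, spec.concession_size_ha, extent, conc_ss[0]
    )
    inactive = random_polygons(
        spec.n_inactive_concessions, spec.concession_size_ha, extent, conc_ss[1]
    )
    concession_polygons = VectorLayer(
        active + inactive,
        [{"status": "active"} for _ in active]
        + [{"status": "inactive"} for _ in inactive],
        crs_id=spec.crs_id,
    )
    from .layers import rasterize_polygons  # local import: avoids cycle

    conc_codes = np.zeros((spec.n_rows, spec.n_cols), dtype=np.int16)
    active_mask = rasterize_polygons(concession_polygons.filter(status="active"),
                                     template)
    inactive_mask = rasterize_polygons(concession_polygons.filter(status="inactive"),
                                       template)
    conc_codes[active_mask.cells == 1] = 1
    conc_codes[inactive_mask.cells == 1] = 2  # inactive overrides on overlap
    concessions = ZoneMap(
        grid=template.like(conc_codes, nodata=None),
        zones={0: "none", 1: "active", 2: "inactive"},
    )

    return ScenarioBundle(
        scenario=spec,
        indicator_values=indicator_values,
        categories=categories,
        protected_areas=protected_areas,
        concession_polygons=concession_polygons,
        land_use_plan=land_use_plan,
        concessions=concessions,
    )


# -- bundle I/O -----------------------------------------------------------


def write_bundle(bundle: ScenarioBundle, out_dir: str | Path) -> Path:
    """Write a bundle to a directory: one .asc per raster, GeoJSON per
    vector layer, and a YAML manifest recording the scenario and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ind, grid in bundle.indicator_values.items():
        write_ascii_grid(grid, out / f"indicator_{ind.replace('.', '_')}.asc")
    write_ascii_grid(bundle.land_use_plan.grid, out / "land_use_plan.asc")
    write_ascii_grid(bundle.concessions.grid, out / "concessions.asc")
    write_geojson(bundle.protected_areas, out / "protected_areas.geojson")
    write_geojson(bundle.concession_polygons, out / "concessions.geojson")
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(
        yaml.safe_dump(bundle.manifest(), sort_keys=True)
    )
    return manifest_path


def manifest_hash(out_dir: str | Path) -> str:
    """SHA-256 over the manifest and every raster/vector file in a bundle
    directory, for byte-identity checks between runs."""
    out = Path(out_dir)
    digest = hashlib.sha256()
    for path in sorted(out.rglob("*")):
        if path.is_file():
            digest.update(path.name.encode())
            digest.update(path.read_bytes())
    return digest.hexdigest()
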