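"""Composite spatial indicator layers.

Some indicators cannot be classified cell-by-cell from a single value:
they need geometry — distance buffers around protected areas, minimum
contiguous forest-block areas, tiered species-range overlays.  This
module builds those rank-encoded risk layers from binary masks.

All distances are Euclidean between cell centers; buffer membership
means the cell center lies within the given distance of the center of
some source cell.  Areas are cell counts times the cell area in
hectares, which is exact under the assumed equal-area projected CRS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely import contains_xy
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .grid import (
    CLASS_NODATA,
    CRSMismatchError,
    Grid,
    VectorLayer,
    require_congruent,
)
from .rules import RiskClass

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def rasterize_polygons(polygons: VectorLayer | list[BaseGeometry], template: Grid) -> Grid:
    """Burn polygons onto the template grid by the cell-center rule.

    A cell is 1 iff its center falls inside (or on the boundary of) any
    polygon.  Raises :class:`CRSMismatchError` when the vector layer
    declares a CRS different from the template's.
    """
    if isinstance(polygons, VectorLayer):
        if (
            polygons.crs_id is not None
            and template.crs_id is not None
            and polygons.crs_id != template.crs_id
        ):
            raise CRSMismatchError(
                f"vector CRS {polygons.crs_id!r} != raster CRS {template.crs_id!r}"
            )
        geoms = polygons.geometries
    else:
        geoms = list(polygons)
    out = np.zeros((template.n_rows, template.n_cols), dtype=np.uint8)
    if geoms:
        union = unary_union(geoms)
        xs, ys = template.cell_centers()
        # boundary-touching centers count as inside
        inside = contains_xy(union, xs.ravel(), ys.ravel()) | contains_xy(
            union.boundary, xs.ravel(), ys.ravel()
        )
        out = inside.reshape(out.shape).astype(np.uint8)
    return template.like(out, nodata=CLASS_NODATA)


def distance_buffer(mask: Grid, distance_m: float) -> Grid:
    """Cells whose center lies within ``distance_m`` of any 1-cell's center.

    Exact Euclidean distance transform; source cells are always included
    (distance 0), so ``distance_m = 0`` is the identity.  Nodata cells
    neither seed the buffer nor receive it.
    """
    if distance_m < 0:
        raise ValueError(f"buffer distance must be >= 0, got {distance_m}")
    valid = mask.valid_mask()
    src = (mask.cells == 1) & valid
    if src.any():
        dist = ndimage.distance_transform_edt(
            ~src, sampling=(mask.cell_size, mask.cell_size)
        )
        # tiny relative tolerance: EDT is exact in theory but float sqrt
        # can land a hair above d at exact-hit distances
        out = (dist <= distance_m * (1 + 1e-9)).astype(np.uint8)
    else:
        out = np.zeros(mask.cells.shape, dtype=np.uint8)
    out[~valid] = CLASS_NODATA
    return mask.like(out, nodata=CLASS_NODATA)


@dataclass
class LabeledRegions:
    """Connected regions of a binary mask with per-region areas."""

    labels: Grid  # int labels, 0 = background
    areas_ha: dict[int, float]  # label -> area in hectares
    connectivity: int

    @property
    def n_regions(self) -> int:
        return len(self.areas_ha)


def connected_components(mask: Grid, connectivity: int = 8) -> LabeledRegions:
    """Label maximal connected regions of 1-cells (4- or 8-connected)."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    src = (mask.cells == 1) & mask.valid_mask()
    labels, n = ndimage.label(src, structure=_STRUCTURES[connectivity])
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    areas = {lab: float(counts[lab]) * mask.cell_area_ha for lab in range(1, n + 1)}
    return LabeledRegions(
        labels=mask.like(labels.astype(np.int32), nodata=None),
        areas_ha=areas,
        connectivity=connectivity,
    )


def _class_layer(template: Grid, ranks: np.ndarray) -> Grid:
    out = ranks.astype(np.uint8)
    out[~template.valid_mask()] = CLASS_NODATA
    return template.like(out, nodata=CLASS_NODATA)


def build_protection_layer(protected_mask: Grid, buffer_m: float = 1000.0) -> Grid:
    """Formal protection indicator: protected cells are VERY_HIGH risk,
    a buffer ring around them (default 1 km) is MEDIUM, everything else
    LOW."""
    buffered = distance_buffer(protected_mask, buffer_m)
    protected = protected_mask.cells == 1
    ranks = np.zeros(protected_mask.cells.shape, dtype=np.uint8)
    ranks[buffered.cells == 1] = RiskClass.MEDIUM.rank
    ranks[protected] = RiskClass.VERY_HIGH.rank
    return _class_layer(protected_mask, ranks)


def build_forest_block_layer(
    forest_mask: Grid,
    endangered_ecosystem_mask: Grid | None = None,
    ecotone_count: Grid | None = None,
    rare_ecosystem_mask: Grid | None = None,
    min_block_ha: float = 20_000.0,
    buffer_m: float = 3000.0,
    connectivity: int = 8,
) -> Grid:
    """Intact-forest / endangered-ecosystem indicator.

    Per-cell maximum of three tiers: MEDIUM where the cell belongs to a
    contiguous forest block larger than ``min_block_ha`` (strictly) or
    lies within ``buffer_m`` of one; HIGH where two or more ecotone
    regions meet or an endangered ecosystem is present; VERY_HIGH on
    rare ecosystems (karst, peat, freshwater swamp, mangrove, heath or
    cloud forest).  Block area is measured before buffering: the buffer
    ring inherits MEDIUM but never helps a block across the threshold.
    """
    grids = [g for g in (forest_mask, endangered_ecosystem_mask, ecotone_count,
                         rare_ecosystem_mask) if g is not None]
    require_congruent(grids, "build_forest_block_layer")
    regions = connected_components(forest_mask, connectivity)
    big = {lab for lab, a in regions.areas_ha.items() if a > min_block_ha}
    big_mask = np.isin(regions.labels.cells, sorted(big)).astype(np.uint8)
    buffered = distance_buffer(forest_mask.like(big_mask, nodata=None), buffer_m)

    ranks = np.zeros(forest_mask.cells.shape, dtype=np.uint8)
    ranks[buffered.cells == 1] = RiskClass.MEDIUM.rank
    high = np.zeros_like(ranks, dtype=bool)
    if ecotone_count is not None:
        high |= (ecotone_count.cells >= 2) & ecotone_count.valid_mask()
    if endangered_ecosystem_mask is not None:
        high |= endangered_ecosystem_mask.cells == 1
    ranks[high] = np.maximum(ranks[high], RiskClass.HIGH.rank)
    if rare_ecosystem_mask is not None:
        ranks[rare_ecosystem_mask.cells == 1] = RiskClass.VERY_HIGH.rank
    return _class_layer(forest_mask, ranks)


def build_species_layer(
    distribution_mask: Grid,
    habitat_mask: Grid | None = None,
    critical_site_mask: Grid | None = None,
) -> Grid:
    """Protected/endangered species indicator: distribution overlap is
    MEDIUM, habitat overlap HIGH, breeding/nesting or other critical
    sites VERY_HIGH; per-cell maximum of the tiers, LOW where none."""
    grids = [g for g in (distribution_mask, habitat_mask, critical_site_mask)
             if g is not None]
    require_congruent(grids, "build_species_layer")
    ranks = np.zeros(distribution_mask.cells.shape, dtype=np.uint8)
    ranks[distribution_mask.cells == 1] = RiskClass.MEDIUM.rank
    if habitat_mask is not None:
        ranks[habitat_mask.cells == 1] = np.maximum(
            ranks[habitat_mask.cells == 1], RiskClass.HIGH.rank
        )
    if critical_site_mask is not None:
        ranks[critical_site_mask.cells == 1] = RiskClass.VERY_HIGH.rank
    return _class_layer(distribution_mask, ranks)
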