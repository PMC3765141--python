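"""Raster container and plain-text geospatial I/O.

All spatial layers in the pipeline are square-celled rasters in a shared
projected, equal-area coordinate system.  Rasters are exchanged as ESRI
ASCII grids (``.asc``) with an optional JSON sidecar carrying the CRS
identifier and the value-encoding kind; polygons are exchanged as GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

#: uint8 sentinel for missing cells in class-encoded rasters.
CLASS_NODATA = 255


class GridCongruenceError(ValueError):
    """Raised when layers entering an overlay disagree on geometry."""


class CRSMismatchError(ValueError):
    """Raised when vector and raster inputs declare different CRSs."""


@dataclass
class Grid:
    """A georeferenced single-band raster with square cells.

    Parameters
    ----------
    cells
        2-D array of values. Float arrays use NaN (or ``nodata``) for
        missing cells; integer class arrays use ``nodata`` (255 for
        rank-encoded risk classes).
    x_origin, y_origin
        Map coordinates of the *upper-left corner* of the upper-left cell.
    cell_size
        Cell edge length in metres. Cells are square; the CRS is assumed
        projected and equal-area, so ``cell_area_ha`` is exact.
    nodata
        Sentinel marking missing cells, compared with ``==`` for integer
        grids; NaN is always treated as missing in float grids.
    crs_id
        Free-form identifier of the projected CRS (e.g. ``"EPSG:32749"``).
    """

    cells: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 100.0
    nodata: float | int | None = None
    crs_id: str | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.cells.ndim != 2:
            raise ValueError("Grid cells must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.cells.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cells.shape[1]

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 10_000.0

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of every cell center as (xs, ys) 2-D arrays."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        xs = self.x_origin + (cols + 0.5) * self.cell_size
        ys = self.y_origin - (rows + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def valid_mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        valid = np.ones(self.cells.shape, dtype=bool)
        if np.issubdtype(self.cells.dtype, np.floating):
            valid &= ~np.isnan(self.cells.astype(float))
        if self.nodata is not None and not (
            isinstance(self.nodata, float) and np.isnan(self.nodata)
        ):
            valid &= self.cells != self.nodata
        return valid

    def total_mapped_area_ha(self) -> float:
        return float(self.valid_mask().sum()) * self.cell_area_ha

    def congruent_with(self, other: "Grid") -> bool:
        return (
            self.cells.shape == other.cells.shape
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.cell_size, other.cell_size)
            and (
                self.crs_id is None
                or other.crs_id is None
                or self.crs_id == other.crs_id
            )
        )

    def like(self, cells: np.ndarray, nodata=None) -> "Grid":
        """New grid sharing this grid's georeferencing."""
        return replace(self, cells=np.asarray(cells), nodata=nodata)


def require_congruent(grids: Iterable[Grid], context: str = "operation") -> None:
    grids = list(grids)
    first = grids[0]
    for g in grids[1:]:
        if not first.congruent_with(g):
            raise GridCongruenceError(
                f"{context}: grids disagree on shape/origin/cell size/CRS "
                f"({first.cells.shape}@{first.cell_size} m vs "
                f"{g.cells.shape}@{g.cell_size} m)"
            )


# -- ESRI ASCII grid I/O --------------------------------------------------


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write as ESRI ASCII grid plus a ``.aux.json`` sidecar.

    The sidecar stores ``crs_id`` and the array dtype kind, which the
    ``.asc`` header cannot carry.
    """
    path = Path(path)
    nodata = grid.nodata
    if nodata is None:
        nodata = -9999 if np.issubdtype(grid.cells.dtype, np.floating) else CLASS_NODATA
    cells = grid.cells
    if np.issubdtype(cells.dtype, np.floating):
        cells = np.where(np.isnan(cells.astype(float)), nodata, cells)
    y_ll = grid.y_origin - grid.n_rows * grid.cell_size
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x_origin!r}\n"
        f"yllcorner {y_ll!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    is_int = np.issubdtype(grid.cells.dtype, np.integer)
    fmt = "%d" if is_int else "%.10g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, cells, fmt=fmt)
    sidecar = {"crs_id": grid.crs_id, "dtype": "int" if is_int else "float"}
    Path(str(path) + ".aux.json").write_text(json.dumps(sidecar))


def read_ascii_grid(path: str | Path) -> Grid:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"}:
                header[key] = float(value)
                pos = fh.tell()
            else:  # optional NODATA line missing
                break
        fh.seek(pos)
        body = np.loadtxt(fh, ndmin=2)
    crs_id = None
    dtype = "float"
    sidecar_path = Path(str(path) + ".aux.json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        crs_id = sidecar.get("crs_id")
        dtype = sidecar.get("dtype", "float")
    nodata = header.get("nodata_value")
    if dtype == "int":
        body = body.astype(np.int64)
        if nodata is not None:
            nodata = int(nodata)
        if nodata == CLASS_NODATA:
            body = body.astype(np.uint8)
    cell_size = header["cellsize"]
    n_rows = int(header["nrows"])
    return Grid(
        cells=body,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + n_rows * cell_size,
        cell_size=cell_size,
        nodata=nodata,
        crs_id=crs_id,
    )


# -- GeoJSON I/O ----------------------------------------------------------


@dataclass
class VectorLayer:
    """A set of polygon features with per-feature attributes."""

    geometries: list[BaseGeometry] = field(default_factory=list)
    properties: list[dict] = field(default_factory=list)
    crs_id: str | None = None

    def __post_init__(self) -> None:
        if not self.properties:
            self.properties = [{} for _ in self.geometries]
        if len(self.properties) != len(self.geometries):
            raise ValueError("one properties dict per geometry required")

    def __len__(self) -> int:
        return len(self.geometries)

    def filter(self, **attrs) -> "VectorLayer":
        """Features whose properties match all given key=value pairs."""
        keep = [
            i
            for i, props in enumerate(self.properties)
            if all(props.get(k) == v for k, v in attrs.items())
        ]
        return VectorLayer(
            [self.geometries[i] for i in keep],
            [self.properties[i] for i in keep],
            self.crs_id,
        )


def write_geojson(layer: VectorLayer, path: str | Path) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": props}
        for geom, props in zip(layer.geometries, layer.properties)
    ]
    doc: dict = {"type": "FeatureCollection", "features": features}
    if layer.crs_id is not None:
        doc["crs"] = {"type": "name", "properties": {"name": layer.crs_id}}
    Path(path).write_text(json.dumps(doc))


def read_geojson(path: str | Path) -> VectorLayer:
    doc = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in doc.get("features", [])]
    props = [f.get("properties") or {} for f in doc.get("features", [])]
    crs_id = None
    if "crs" in doc:
        crs_id = doc["crs"].get("properties", {}).get("name")
    return VectorLayer(geoms, props, crs_id)
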