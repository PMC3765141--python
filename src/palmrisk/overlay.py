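"""Risk Indicator Map assembly and zonal reporting.

The per-indicator risk layers are combined by Liebig's law of the
minimum, applied to suitability: a cell's combined class is the *worst*
(highest-risk) class among its indicator layers, because a single
violated criterion is enough to make expansion non-compliant.  The
combined raster is the Risk Indicator Map (RIM).

The RIM is then tabulated (area and share per class), cross-tabulated
against analysis zones (concession status, provincial land-use-plan
classes), and turned into a ranked list of expansion options following
the legal practicability order: land for other use (APL) first, then
conversion forest (HPK), production forest (HP/HPT), and finally forest
with a protection function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import CLASS_NODATA, Grid, require_congruent
from .rules import RISK_CLASSES, RiskClass

#: Legal land-use-plan classes in fixed priority order (most to least
#: practicable for plantation development).
LEGAL_PRIORITY = (
    "other use",
    "conversion forest",
    "production forest",
    "protection forest",
)

CONCESSION_LABELS = ("none", "active", "inactive")


class UnknownZoneError(ValueError):
    """A zone raster contains codes absent from its zone dictionary."""


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def combine_liebig(layers: Sequence[Grid], nodata_policy: str = "ignore") -> Grid:
    """Combine rank-encoded risk layers by per-cell maximum risk.

    Under ``nodata_policy="ignore"`` a cell is NODATA only where *every*
    layer is NODATA (layers with partial coverage still contribute
    elsewhere); under ``"propagate"`` NODATA in any layer blanks the
    cell.  The result is invariant under permutation and duplication of
    the layer list.
    """
    layers = list(layers)
    if not layers:
        raise ValueError("combine_liebig needs at least one layer")
    if nodata_policy not in {"ignore", "propagate"}:
        raise ValueError(f"unknown nodata_policy: {nodata_policy!r}")
    require_congruent(layers, "combine_liebig")
    stack = np.stack([lyr.cells.astype(np.uint8) for lyr in layers])
    valid = np.stack([lyr.valid_mask() for lyr in layers])
    masked = np.where(valid, stack, 0)
    out = masked.max(axis=0).astype(np.uint8)
    if nodata_policy == "ignore":
        blank = ~valid.any(axis=0)
    else:
        blank = ~valid.all(axis=0)
    out[blank] = CLASS_NODATA
    return layers[0].like(out, nodata=CLASS_NODATA)


@dataclass
class AreaTable:
    """Per-class areas (ha) and integer percentage shares for one raster
    or one zone.

    ``denominator_ha`` is the base for the percentage shares; by default
    the row's own total, but zonal rows of a province-wide report use
    the whole mapped area so that shares across zones are comparable.
    Percentages are rounded half-up to integers.
    """

    label: str
    area_ha: dict[RiskClass, float]
    denominator_ha: float | None = None

    @property
    def total_ha(self) -> float:
        return float(sum(self.area_ha.values()))

    @property
    def percent(self) -> dict[RiskClass, int]:
        denom = self.denominator_ha if self.denominator_ha else self.total_ha
        if denom == 0:
            return {c: 0 for c in RISK_CLASSES}
        return {
            c: round_half_up(100.0 * self.area_ha.get(c, 0.0) / denom)
            for c in RISK_CLASSES
        }

    def as_row(self) -> dict:
        pct = self.percent
        row: dict = {"label": self.label}
        for c in RISK_CLASSES:
            row[f"{c.name.lower()}_ha"] = self.area_ha.get(c, 0.0)
        for c in RISK_CLASSES:
            row[f"{c.name.lower()}_pct"] = pct[c]
        row["total_ha"] = self.total_ha
        return row


def area_tables_to_frame(tables: Iterable[AreaTable]) -> pd.DataFrame:
    return pd.DataFrame([t.as_row() for t in tables])


def tabulate(layer: Grid, label: str = "") -> AreaTable:
    """Per-class area of a rank-encoded layer; NODATA cells excluded."""
    valid = layer.valid_mask()
    counts = np.bincount(layer.cells[valid].astype(np.int64), minlength=4)
    areas = {c: float(counts[c.rank]) * layer.cell_area_ha for c in RISK_CLASSES}
    return AreaTable(label=label, area_ha=areas)


@dataclass
class ZoneMap:
    """Categorical raster of analysis zones with a code dictionary."""

    grid: Grid
    zones: dict[int, str] = field(default_factory=dict)

    def check_codes(self) -> None:
        valid = self.grid.valid_mask()
        present = np.unique(self.grid.cells[valid]).astype(int)
        unknown = sorted(int(c) for c in present if int(c) not in self.zones)
        if unknown:
            raise UnknownZoneError(
                f"zone raster contains codes not in the zone dictionary: {unknown}"
            )

    def mask_for(self, *labels: str) -> np.ndarray:
        codes = [c for c, lab in self.zones.items() if lab in labels]
        return np.isin(self.grid.cells, codes) & self.grid.valid_mask()


def cross_tabulate(
    rim: Grid,
    zones: ZoneMap,
    denominator_ha: float | None = None,
) -> list[AreaTable]:
    """One AreaTable per zone over the RIM cells falling in that zone.

    With ``denominator_ha`` unset each zone's shares use its own total;
    pass the whole mapped area to report shares of the province instead.
    """
    require_congruent([rim, zones.grid], "cross_tabulate")
    zones.check_codes()
    valid = rim.valid_mask() & zones.grid.valid_mask()
    out = []
    for code in sorted(zones.zones):
        in_zone = valid & (zones.grid.cells == code)
        counts = np.bincount(rim.cells[in_zone].astype(np.int64), minlength=4)
        areas = {c: float(counts[c.rank]) * rim.cell_area_ha for c in RISK_CLASSES}
        out.append(
            AreaTable(
                label=zones.zones[code],
                area_ha=areas,
                denominator_ha=denominator_ha,
            )
        )
    return out


@dataclass
class RecommendationRow:
    priority: int
    zone_label: str
    low_risk_ha: float


@dataclass
class RecommendationTable:
    """Ranked low-risk expansion options.

    Row 1 is the first-call option: low-risk land inside inactive
    concessions (already under license application, no new allocation
    needed).  The remaining rows rank low-risk land *outside existing
    concessions* by legal land-use-plan class, in the fixed
    practicability order other use > conversion forest > production
    forest > protection forest.
    """

    rows: list[RecommendationRow]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"priority": r.priority, "zone": r.zone_label,
                 "low_risk_ha": r.low_risk_ha}
                for r in self.rows
            ]
        )


def rank_expansion_options(
    rim: Grid,
    land_use_plan: ZoneMap,
    concessions: ZoneMap,
) -> RecommendationTable:
    """Rank low-risk expansion options by concession status and legal class."""
    require_congruent([rim, land_use_plan.grid, concessions.grid],
                      "rank_expansion_options")
    land_use_plan.check_codes()
    concessions.check_codes()
    bad = [lab for lab in land_use_plan.zones.values() if lab not in LEGAL_PRIORITY]
    if bad:
        raise UnknownZoneError(
            f"land-use-plan zone labels not in the legal classes "
            f"{LEGAL_PRIORITY}: {sorted(set(bad))}"
        )
    bad = [lab for lab in concessions.zones.values() if lab not in CONCESSION_LABELS]
    if bad:
        raise UnknownZoneError(
            f"concession zone labels not in {CONCESSION_LABELS}: {sorted(set(bad))}"
        )
    low = (rim.cells == RiskClass.LOW.rank) & rim.valid_mask()
    cell_ha = rim.cell_area_ha

    rows = [
        RecommendationRow(
            priority=1,
            zone_label="inactive concessions",
            low_risk_ha=float((low & concessions.mask_for("inactive")).sum()) * cell_ha,
        )
    ]
    outside = ~concessions.mask_for("active", "inactive")
    for i, legal in enumerate(LEGAL_PRIORITY, start=2):
        in_class = land_use_plan.mask_for(legal)
        rows.append(
            RecommendationRow(
                priority=i,
                zone_label=legal,
                low_risk_ha=float((low & outside & in_class).sum()) * cell_ha,
            )
        )
    return RecommendationTable(rows=rows)
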