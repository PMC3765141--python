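"""Published West Kalimantan case-study tabulation.

The methodology was originally applied to the province of West
Kalimantan (Indonesia) on seven indicator layers derived from
provincial GIS data.  The underlying rasters are proprietary and not
redistributable, but the published per-class area tabulation — the
seven indicator rows, the combined Risk Indicator Map (RIM) row, and
the two zonal rows (RIM over inactive concessions; RIM over other-use
land outside existing concessions) — ships with the package as
reference data.

These printed hectare figures are *inputs*: the functions here recompute
the derived quantities (percentage shares, the Liebig low-area bound,
the inactive-concession very-high share) from them, which is how the
arithmetic of the case study is checked without access to the source
rasters.  Zonal-row shares are expressed against the whole mapped
province area (the RIM row total), not the zone's own total — that is
the convention of the published tabulation.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

from .overlay import round_half_up

#: The seven indicator layers entering the combined map.
INDICATOR_ROWS = ("1.1.1", "1.1.2", "1.1.3", "1.2.1", "1.2.2", "1.2.4", "3.1.1")

_CLASS_COLS = ("low", "medium", "high", "very_high")


def load_west_kalimantan_reference() -> pd.DataFrame:
    """Published per-class areas (ha) and shares (%), indexed by row name."""
    ref = resources.files("palmrisk.data") / "west_kalimantan_areas.csv"
    df = pd.read_csv(StringIO(ref.read_text()))
    return df.set_index("row")


def mapped_area_ha(df: pd.DataFrame | None = None) -> float:
    """Total mapped province area: the combined-map row total."""
    if df is None:
        df = load_west_kalimantan_reference()
    rim = df.loc["rim"]
    return float(sum(rim[f"{c}_ha"] for c in _CLASS_COLS))


def recompute_percentages(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute every percentage share from the published areas.

    Indicator and combined-map rows use their own row total as the
    denominator; zonal rows use the mapped province area.  Rounding is
    half-up to integers.  The result has the same shape as the
    ``*_pct`` columns of the reference frame.
    """
    if df is None:
        df = load_west_kalimantan_reference()
    denom_map = mapped_area_ha(df)
    out = {}
    for row_name, row in df.iterrows():
        total = float(sum(row[f"{c}_ha"] for c in _CLASS_COLS))
        denom = denom_map if row["row_kind"] == "zone" else total
        out[row_name] = {
            f"{c}_pct": round_half_up(100.0 * float(row[f"{c}_ha"]) / denom)
            for c in _CLASS_COLS
        }
    res = pd.DataFrame.from_dict(out, orient="index")
    res.index.name = "row"
    return res


def liebig_low_bound(df: pd.DataFrame | None = None) -> tuple[float, float]:
    """(combined low-risk area, minimum per-indicator low-risk area).

    Under the maximum-risk overlay the combined LOW region is the
    intersection of the per-layer LOW regions, so the first value can
    never exceed the second.
    """
    if df is None:
        df = load_west_kalimantan_reference()
    combined_low = float(df.loc["rim", "low_ha"])
    min_layer_low = float(min(df.loc[r, "low_ha"] for r in INDICATOR_ROWS))
    return combined_low, min_layer_low


def inactive_concession_very_high_share(df: pd.DataFrame | None = None) -> float:
    """Very-high-risk share (%) of the inactive-concession area itself."""
    if df is None:
        df = load_west_kalimantan_reference()
    row = df.loc["rim_inactive_concessions"]
    total = float(sum(row[f"{c}_ha"] for c in _CLASS_COLS))
    return 100.0 * float(row["very_high_ha"]) / total
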